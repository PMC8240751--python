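# Methods

This note documents the models and conventions behind `phantomforge`: what
each stage computes, which parameters matter, what the simulator does and
does not emulate, and where the design was genuinely open.

## Phantom design model

A voxel-printed radiomics phantom renders CT texture by mixing two resins of
opposing attenuation (≈65 and ≈125 HU when scanned) at the printer's droplet
scale. Because a CT voxel (~0.5 × 0.5 × 1 mm) averages thousands of droplets
(48 × 84 × 30 µm), the local resin mixing fraction controls the
reconstructed HU almost linearly. The design pipeline therefore works in a
**mix-ratio** unit: each tumor ROI is min–max normalized over its own
in-mask voxels to [0, 1], composited into the background, and that ratio
field is what gets halftoned.

Conventions and choices:

- **Axis order** is (z, y, x) everywhere; every format reader converts into
  it. One convention, no transposition bugs between imaging and printing.
- **Normalization is per-ROI min–max** over in-mask voxels, not a fixed HU
  window: each segment is normalized individually, so every printed tumor
  spans the full two-resin range. A constant ROI has no range; it falls back
  to mid-mixture 0.5 with a warning rather than failing.
- **Compositing** replaces background voxels inside each placed mask with
  ROI values and touches nothing else (asserted bit-for-bit in tests).
  Placements are user-specified offsets; overlapping masks are rejected
  because the replacement would be ambiguous. Compositing works in HU or in
  ratio units, but all inputs must carry the same unit tag.
- **Disc support**: the part is an axis-aligned cylinder (default 180 mm ×
  40 mm) centered in the grid; outside it the mix ratio is forced to 0 and
  the support mask is carried through rasterization so no material is
  deposited off the part.

## Print preparation

**Supersampling.** The design is brought to the droplet grid with
Whittaker–Shannon (sinc) interpolation. Integer upsampling factors use
exact FFT zero-padding (with the even-length Nyquist bin split to keep the
result real, and a linear phase applied so output samples sit at voxel
centers of the same field of view); non-integer factors fall back to a
Lanczos-3 windowed sinc with edge replication. On band-limited periodic
inputs the FFT path is exact to ~1e-12; the tests assert 1e-6 on analytic
sinusoids. Downsampling is rejected — the printer grid is always finer.

**Dithering.** Each layer is binarized by Floyd–Steinberg error diffusion:
raster (non-serpentine) scan order, threshold 0.5, weights 7/16 (right),
3/16 (down-left), 5/16 (down), 1/16 (down-right). At the slice border the
weights of the remaining in-bounds neighbors are renormalized to sum to 1,
so quantization error is never lost off the edge; the slice mean is then
conserved to within the last pixel's residual (|mean out − mean in| <
1/pixel-count, asserted for uniform gray levels 0, 0.1, …, 1). The
algorithm is deterministic: identical input yields bit-identical bitmaps.

**Material stacks.** The dithered bitmap is the deposition map of the
high-attenuation resin (mix ratio 1 = brightest tissue); the second resin's
bitmap is its bitwise inversion within the part support, and the third
channel is all zeros — two materials of opposing density are enough for the
contrast range. Which physical resin receives the "1" channel is
printer-specific, so `build_material_stacks(one_is_high_attenuation=False)`
swaps the two. Dithering is per-layer 2D, matching how the printer consumes
one bitmap per layer; 3D error diffusion is deliberately not used.

## Radiomic features

Six features, chosen for their prognostic track record in lung and
pancreatic cancer imaging:

| feature | definition |
|---|---|
| energy | Σ v² over in-mask voxels (raw intensities) |
| entropy | −Σ p_b log₂ p_b over discretized-level frequencies |
| GLCM contrast | Σ (i−j)² p(i,j), distance-1, symmetric, 13-direction mean |
| GLCM dissimilarity | Σ \|i−j\| p(i,j), same matrices |
| GLRLM GLN | Σ_i (Σ_j r(i,j))² / N_runs, 13-direction mean |
| wavelet HLH GLN | GLRLM GLN of the HLH coiflet-1 subband |

**Discretization** uses a fixed bin width (default 25 HU) with bin edges on
absolute multiples of the bin width, re-indexed so the lowest occupied bin
is level 1. The alternative — anchoring edges at the per-image in-mask
minimum — makes every level boundary a function of a single extreme voxel;
across repeat scans the minimum jitters by 1–2 HU and drags every bin edge
through the histogram, which destabilizes entropy and the GLN features by
whole percent. Aligned edges decouple the level map from sampling extremes:
every feature here is invariant to the joint index shift that remains.

**Directions.** The 26-neighborhood offsets collapse, modulo sign, to 13
unique directions (asserted by enumeration). GLCM matrices are built per
direction from in-mask voxel pairs at distance 1, accumulated symmetrically
and normalized; GLRLM runs are maximal collinear in-mask constant-level
segments. Feature values are the unweighted mean over directions
(feature-level averaging, not merged matrices); a direction with zero valid
pairs is excluded from the mean with a warning. Because GLN depends only on
the *number* of runs per level, it is computed from run starts (a voxel
whose backward neighbor leaves the mask or the level), which is exact and
fully vectorized; an explicit run-walking oracle confirms equality on all
512 two-level 2×2×2 volumes.

**Wavelet.** One-level undecimated 3D decomposition: plain correlation with
the coiflet-1 decomposition filters along each axis, no downsampling,
symmetric (reflect) boundaries, output on the input grid. The HLH label is
assigned in x-y-z order (first letter filters the x axis); toolkits differ
on this convention, so `wavelet_axis_order="zyx"` exposes the other
reading. The subband is discretized with the same bin-width rule before the
run-length statistics.

**Patchwise mode** tiles the ROI bounding box into non-overlapping patches
of 2 mm per side (voxel count = round(mm/spacing), min 1), computes each
feature per patch over that patch's in-mask voxels, and averages patches
with ≥50% mask coverage (mean chosen as the least-structured aggregate; the
threshold is exposed). Patches clipped at the box edge can be one voxel
thin, which cannot carry the length-6 wavelet filter — the patchwise mode
is intended for the first-order and co-occurrence features.

No resampling or smoothing precedes extraction; features are computed on
the images as given.

## QC statistics

- **wCV** = σ_w/μ × 100. Per ROI, σ_w is the sample SD across replicates
  and μ their mean; the pooled estimate uses the mean of per-ROI variances
  (balanced design) and the grand mean. wCV < 10% is flagged repeatable.
  Replicate values are pivot-shifted before the variance so bit-identical
  replicates give exactly 0.
- **wCV 95% CI** uses χ² as the pivotal statistic:
  bound = wCV·√(dof/χ²_{dof,α}) with dof = N·(replicates−1) and lower-tail
  quantile probabilities α = 0.975 (lower) and 0.025 (upper). Simulation
  at a true wCV of 5% (5 ROIs × 30 replicates, 1000 experiments) shows
  92–98% coverage, as a 95% interval should.
- **pDV** = (f̄_new − f̂_ref)/f̂_ref × 100, the plain relative deviation of
  the scan-mode mean from the reference mean.
- **Wilcoxon signed-rank** (one-sample, two-sided): zero differences are
  dropped (classic convention, not Pratt), ties get mid-ranks. For n ≤ 12
  the null distribution is enumerated exactly over all 2ⁿ sign patterns;
  beyond that, the normal approximation with tie correction and a 0.5
  continuity correction. The approximation Z is always reported — it feeds
  the effect size r = Z/√N_obs (clipped to [−1, 1] with a warning if the
  tie-corrected variance ever pushes it out). Effect-size CIs use a
  percentile bootstrap, 100 resamples by default, seeded.
- **SSIM** uses the original publication's parameters: Gaussian window
  σ = 1.5 (11 taps), K1 = 0.01, K2 = 0.03 over a stated dynamic range
  (delegated to scikit-image; cross-checked against the constant-image
  closed form).

No multiple-testing correction is applied, deliberately: the workflow
reports per-feature, per-mode deviations as a QC panel, not a hypothesis
screen.

## Scan simulator

The simulator exists so the pipeline and statistics are exercisable without
a printer or scanner. It is phenomenological by design: image-domain
perturbations, not CT physics (no sinogram, no beam hardening, no bow-tie
model).

**Digital phantom.** A disc-supported background of band-passed Gaussian
texture scaled into [65, 125] HU — the range the two printed resins span —
with blob-shaped lesions (spheres with a smooth bounded radial
perturbation). Lesion centers sit on a jittered ring, which keeps large
lesions disjoint by construction while preserving the arbitrary feel of
manual placement; placement falls back to rejection retries and fails
loudly if geometry cannot fit. Lesion texture is a structure + fine-scale
mixture rank-mapped to a uniform histogram over the full 65–125 band: a
printed tumor is individually normalized to the full ratio range, and the
patient image it reproduces carries fine-grained image noise, so a broad
histogram with voxel-scale roughness is the realistic emulation. Everything
is a pure function of (geometry, seed). The default extent (64 × 192 × 192
voxels at 1 mm) hosts five lesions of ≥32³ voxels, the scale used by the
acceptance computation; tests use smaller geometries.

**Repeat scans** add independent Gaussian noise per replicate (default
σ = 5 HU — small against the 60 HU dynamic range, mirroring a stable
abdominal protocol; a simulator choice, not a measured value). Optionally
the noise field is smoothed and rescaled to emulate the spatial correlation
of reconstruction noise; the per-voxel SD stays σ either way.

**Scan modes** apply, in order: dose-scaled noise (σ/√dose, the quantum
noise law), Gaussian smoothing (iterative-reconstruction analogue),
unsharp-mask boost (sharp kernel analogue), in-plane resampling to a new
pixel size (display-FOV analogue; 350 mm / 512 = 0.684 mm), and a linear
shading field (off-center analogue). Neutral parameters skip their stage,
so the baseline preset is an exact identity. Preset magnitudes are chosen
to preserve qualitative orderings (more smoothing → smoother; less dose →
noisier); they are not calibrated to any scanner's MTF or NPS, and
dual-energy reconstruction is represented only as a generic
noise + smoothing + boost combination.

**What passing tests show — and don't.** The simulator demonstrates that
the pipeline's statistics behave correctly under known perturbations
(zero noise → zero wCV; monotone noise → monotone contrast; features
repeatable under low-amplitude noise). It does not model fat planes, bone,
contrast agents, motion, or scanner-specific artifacts, so absolute pDV
magnitudes from the simulator are not predictions for any physical scanner.

## Numerical notes

- Grid tolerance for mask/volume matching: 1e-3 mm on spacing and origin
  (absorbs format rounding); raster spacing must match the printer spec to
  1e-6 mm.
- RATIO volumes are clipped to [0, 1] after sinc interpolation (ringing can
  overshoot by ~1e-3 near sharp edges).
- Volume round trips preserve integer HU exactly and ratios to 1e-6;
  raster stacks round-trip bit-exactly (1-bit PNG is lossless).
- Degenerate inputs fail loudly and early: empty masks, zero reference
  means, non-binary bitmaps, dof < 1, downsampling requests.

## Known limitations

- The printer-vendor job format is out of scope; 1-bit PNGs plus a JSON
  manifest are the interface.
- DICOM intake handles single-frame CT series only (no DICOM-SEG/RTSTRUCT,
  no enhanced multi-frame).
- The wavelet-GLN feature inherits every instability of run-length
  statistics on high-pass fields; it is the least robust feature in the
  panel under scan-mode perturbation, which is precisely why it is worth
  auditing.
- Physical print validation — resin HU drift, droplet placement error,
  scanner PSF — is outside the digital pipeline.
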