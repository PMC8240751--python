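# phantomforge

Tools for building **anatomically informed, voxel-printed CT radiomics
phantoms** and for auditing how repeatable and reproducible radiomic
features are on them.

Radiomic features — quantitative descriptors of intensity and texture
extracted from CT images — are only useful as biomarkers if they survive a
rescan. A printed phantom that reproduces real tumor texture lets a clinic
measure that directly: print a disc whose two resins render patient-derived
texture, scan it repeatedly and under different scan modes, and quantify how
each feature moves. `phantomforge` implements the digital side of that
workflow end to end:

1. **Intake** (`volume_io`) — DICOM series → Hounsfield-unit volumes;
   NIfTI/NRRD volumes and masks; 1-bit PNG raster stacks with a JSON
   manifest for the printer.
2. **Design** (`phantom_design`) — crop tumor ROIs at their mask bounding
   box, min–max normalize each to a material mix ratio in [0, 1], composite
   them into a background, cut the result to a disc (default 180 × 40 mm).
3. **Print prep** (`print_prep`) — Whittaker–Shannon (sinc) supersampling to
   the droplet grid (48 × 84 × 30 µm), Floyd–Steinberg error-diffusion
   dithering per layer, and three material bitmap stacks: A = dithered
   mixture, B = its inversion inside the part, C = all zeros.
4. **Features** (`radiomics`) — the six-feature prognostic panel:
   first-order energy and entropy, GLCM contrast and dissimilarity, GLRLM
   gray-level non-uniformity (GLN), and GLN of the HLH coiflet-1 wavelet
   subband; fixed bin width 25, 13-direction averaging, optional 2 mm
   patchwise mode.
5. **QC statistics** (`qc_stats`) — repeatability as the within-subject
   coefficient of variation wCV% = σ_w/μ × 100 with a χ²-pivotal 95% CI
   (repeatable when wCV < 10%); reproducibility as the percent deviation
   pDV% = (f̄_new − f̂_ref)/f̂_ref × 100 with a one-sample Wilcoxon
   signed-rank test, effect size r = Z/√N_obs, and bootstrap CIs; SSIM for
   image-level similarity.
6. **Scan simulation** (`scansim`) — seeded digital phantoms (heterogeneous
   65–125 HU disc, blob lesions), repeat-scan noise, and image-domain
   analogues of clinical scan modes (iterative-reconstruction smoothing,
   sharp kernels, dose-scaled noise, display-FOV pixel-size changes,
   off-center shading), so the whole chain runs without a printer or
   scanner.

## Worked example

`examples/03_repeatability_wcv.py` simulates a fixed two-lesion phantom,
acquires 30 repeat scans with 5 HU Gaussian noise, extracts the six-feature
panel per lesion per scan, and prints the repeatability table:

```
30 repeat scans, 2 lesions, noise sigma 5 HU

feature                roi           wCV %             95% CI  repeatable
energy                 lesion_0      0.105     [0.084, 0.141]  yes
entropy                lesion_0      0.444     [0.354, 0.597]  yes
glcm_contrast          lesion_0      1.121     [0.893, 1.507]  yes
glcm_dissimilarity     lesion_0      0.832     [0.663, 1.119]  yes
glrlm_gln              lesion_0      0.498     [0.397, 0.669]  yes
wavelet_hlh_gln        lesion_0      0.243     [0.193, 0.326]  yes
...
```

Every wCV sits far below the 10% repeatability threshold: on a stable
acquisition the panel is highly repeatable. `examples/04_scan_modes_pdv.py`
shows the complementary result — under perturbed scan modes the texture
features deviate strongly (e.g. GLCM contrast pDV of tens of percent under
added noise or a sharp kernel, negative deviations under smoothing) while
first-order energy barely moves. The other examples demonstrate disc design
plus rasterization (`01`) and feature extraction with the patchwise option
(`02`). Each script runs in seconds and prints what its numbers mean.

A thin CLI wraps the same library calls:

```bash
phantomforge simulate --seed 42 --n-lesions 5 --repeats 30 --out scans/
phantomforge extract  --volume v.nrrd --mask m.nii.gz --out features.csv
phantomforge qc       --features features.csv --reference-mode baseline --out report.csv
```

## Layout

```
src/phantomforge/    library (volume_io, phantom_design, print_prep,
                     radiomics, qc_stats, scansim, pipeline, cli)
examples/            narrative scripts, one per capability
tests/               pytest suite incl. brute-force oracles and
                     end-to-end acceptance checks
docs/methods.md      models, conventions, parameter choices, limitations
```
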