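"""Prognostic radiomic features: first-order, GLCM, GLRLM, wavelet GLN.

Implements the six-feature panel used to audit scanner repeatability:

* first-order **energy** (sum of squared in-mask intensities) and
  **entropy** (Shannon entropy, bits, over fixed-bin-width levels),
* **GLCM contrast** and **dissimilarity** at voxel distance 1, symmetric,
  averaged over the 13 unique 3D directions,
* **GLRLM gray-level non-uniformity** (GLN), same 13-direction average,
* GLN of the **HLH wavelet subband** (one-level undecimated coiflet-1
  decomposition, high-low-high along x, y, z).

Gray levels come from fixed-bin-width discretization with bin edges on
absolute multiples of the bin width, re-indexed so the lowest occupied bin
is level 1. All texture features are invariant to joint level shifts, so
intensity offsets do not move them; energy is not shift-invariant, by
definition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.ndimage import correlate1d

from phantomforge.volume_io import ImageVolume, SegmentationMask

FEATURE_NAMES = (
    "energy",
    "entropy",
    "glcm_contrast",
    "glcm_dissimilarity",
    "glrlm_gln",
    "wavelet_hlh_gln",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings recorded alongside every feature vector.

    bin_width
        Fixed discretization bin width in intensity units (default 25 HU).
    patchwise
        If set, features are computed per 2x2x2 mm patch and averaged.
    wavelet / wavelet_axis_order
        Wavelet family for the HLH subband and which axis receives the
        first subband letter ("xyz": first letter = x-axis filter).
    """

    bin_width: float = 25.0
    n_directions: int = 13
    patchwise: bool = False
    patch_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    min_patch_coverage: float = 0.5
    wavelet: str = "coif1"
    wavelet_subband: str = "HLH"
    wavelet_axis_order: str = "xyz"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_directions != 13:
            raise ValueError("only the 13-direction rotationally averaged set is supported")
        if any(p <= 0 for p in self.patch_size_mm):
            raise ValueError("patch_size_mm must be positive")
        if self.wavelet_axis_order not in ("xyz", "zyx"):
            raise ValueError("wavelet_axis_order must be 'xyz' or 'zyx'")


@dataclass(frozen=True)
class FeatureVector:
    values: dict[str, float]
    config: FeatureConfig
    roi_label: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def direction_offsets() -> list[tuple[int, int, int]]:
    """The 13 unique 3D unit-offset directions (26-neighborhood modulo sign).

    Each offset and its negation describe the same co-occurrence/run
    direction; keeping the lexicographically positive member of each pair
    leaves exactly 13.
    """
    dirs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if d > tuple(-c for c in d):  # keep one representative per +-pair
            dirs.append(d)
    return dirs


def discretize(volume: ImageVolume | np.ndarray, mask: SegmentationMask | np.ndarray,
               bin_width: float = 25.0) -> np.ndarray:
    """Fixed-bin-width gray levels with edges on absolute bin-width multiples.

    A voxel of intensity v falls in bin floor(v / bin_width); levels are
    re-indexed so the lowest occupied in-mask bin is level 1. Out-of-mask
    voxels are 0 (excluded). Shifting all intensities by a multiple of the
    bin width leaves the levels identical; any other shift translates every
    level jointly, which no level-based feature here depends on.

    Anchoring edges to the absolute intensity scale (rather than to the
    in-mask minimum) keeps the level map stable across repeat scans: the
    sample minimum is a noise extreme, and hanging every bin edge off it
    would let a 1-2 HU minimum jitter re-bin a slice of every histogram bin
    in each replicate.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    m = mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask)
    fg = m > 0
    if not fg.any():
        raise ValueError("mask is empty")
    bins = np.floor(data[fg] / bin_width).astype(np.int64)
    levels = np.zeros(data.shape, dtype=np.int64)
    levels[fg] = bins - bins.min() + 1
    return levels


def first_order(volume: ImageVolume | np.ndarray,
                mask: SegmentationMask | np.ndarray,
                bin_width: float = 25.0) -> dict[str, float]:
    """First-order energy and entropy over the in-mask voxels.

    energy  = sum v^2 (raw intensities)
    entropy = -sum p log2 p over discretized-level frequencies
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    m = mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask)
    fg = m > 0
    if not fg.any():
        raise ValueError("mask is empty")
    values = data[fg].astype(np.float64)
    energy = float(np.sum(values**2))
    levels = discretize(data, m, bin_width)[fg]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return {"energy": energy, "entropy": entropy}


def _shift_pairs(levels: np.ndarray, fg: np.ndarray,
                 d: tuple[int, int, int]):
    """In-mask level pairs (levels[v], levels[v+d]) for all valid v."""
    sl_a, sl_b = [], []
    for c, n in zip(d, levels.shape):
        if c >= 0:
            sl_a.append(slice(0, n - c))
            sl_b.append(slice(c, n))
        else:
            sl_a.append(slice(-c, n))
            sl_b.append(slice(0, n + c))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = fg[sl_a] & fg[sl_b]
    return levels[sl_a][valid], levels[sl_b][valid]


def glcm_features(levels: np.ndarray, mask: SegmentationMask | np.ndarray,
                  config: FeatureConfig | None = None) -> dict[str, float]:
    """GLCM contrast and dissimilarity, averaged over the 13 directions.

    Per direction a symmetric, normalized co-occurrence matrix is built from
    in-mask voxel pairs at distance 1; contrast = sum (i-j)^2 p(i,j) and
    dissimilarity = sum |i-j| p(i,j). Directions with no valid pair are
    excluded from the unweighted mean (with a warning).
    """
    m = mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask)
    fg = m > 0
    if fg.sum() < 2:
        raise ValueError("need at least 2 in-mask voxels")
    contrasts, dissims = [], []
    for d in direction_offsets():
        a, b = _shift_pairs(levels, fg, d)
        if a.size == 0:
            warnings.warn(f"direction {d} has no valid voxel pairs; excluded",
                          stacklevel=2)
            continue
        diff = np.abs(a - b).astype(np.float64)
        n_pairs = 2.0 * a.size  # symmetric accumulation
        contrasts.append(float((diff**2).sum() * 2.0 / n_pairs))
        dissims.append(float(diff.sum() * 2.0 / n_pairs))
    if not contrasts:
        raise ValueError("no direction produced a valid voxel pair")
    return {
        "glcm_contrast": float(np.mean(contrasts)),
        "glcm_dissimilarity": float(np.mean(dissims)),
    }


def glcm_matrix(levels: np.ndarray, mask: SegmentationMask | np.ndarray,
                d: tuple[int, int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one direction.

    Exposed for inspection and cross-checks; the feature path sums moments
    of |i-j| directly, which is algebraically identical.
    """
    m = mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask)
    a, b = _shift_pairs(levels, m > 0, d)
    if a.size == 0:
        raise ValueError(f"direction {d} has no valid voxel pairs")
    k = int(levels.max()) + 1
    mat = np.zeros((k, k), dtype=np.float64)
    np.add.at(mat, (a, b), 1.0)
    np.add.at(mat, (b, a), 1.0)
    mat = mat[1:, 1:]
    return mat / mat.sum()


def glrlm_gln(levels: np.ndarray, mask: SegmentationMask | np.ndarray,
              config: FeatureConfig | None = None) -> float:
    """Gray-level non-uniformity, averaged over the 13 run directions.

    Runs are maximal collinear in-mask segments of constant level. With
    r(i, j) the number of runs of level i and length j,
    GLN = sum_i (sum_j r(i,j))^2 / N_runs. Since sum_j r(i,j) is simply the
    number of runs of level i, GLN needs only run starts: a voxel starts a
    run iff its predecessor along the direction is outside the mask or has
    a different level.
    """
    m = mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask)
    fg = m > 0
    if not fg.any():
        raise ValueError("mask is empty")
    glns = []
    for d in direction_offsets():
        # run start: in-mask voxel whose (v - d) neighbor is absent or differs
        same_as_prev = np.zeros(levels.shape, dtype=bool)
        a_idx, b_idx = [], []
        for c, n in zip(d, levels.shape):
            if c >= 0:
                a_idx.append(slice(c, n))       # voxel v
                b_idx.append(slice(0, n - c))   # predecessor v - d
            else:
                a_idx.append(slice(0, n + c))
                b_idx.append(slice(-c, n))
        a_idx, b_idx = tuple(a_idx), tuple(b_idx)
        same_as_prev[a_idx] = (
            fg[a_idx] & fg[b_idx] & (levels[a_idx] == levels[b_idx])
        )
        starts = fg & ~same_as_prev
        runs_per_level = np.bincount(levels[starts])[1:]
        n_runs = runs_per_level.sum()
        glns.append(float((runs_per_level.astype(np.float64) ** 2).sum() / n_runs))
    return float(np.mean(glns))


def _wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(name)
    return np.asarray(w.dec_lo, dtype=np.float64), np.asarray(w.dec_hi, dtype=np.float64)


def wavelet_subband(volume: ImageVolume | np.ndarray, subband: str = "HLH",
                    wavelet: str = "coif1",
                    axis_order: str = "xyz") -> np.ndarray:
    """One-level undecimated 3D wavelet subband, output on the input grid.

    ``subband`` letters name the low/high-pass filter per axis in
    ``axis_order`` ("xyz": first letter filters along x). Filtering is plain
    correlation with the decomposition filters (no downsampling), symmetric
    boundary handling.
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    if any(n < 2 for n in data.shape):
        raise ValueError(f"degenerate axis in shape {data.shape}; need >=2 voxels per axis")
    if len(subband) != 3 or any(c not in "LH" for c in subband):
        raise ValueError(f"subband must be three letters from {{L,H}}, got {subband!r}")
    lo, hi = _wavelet_filters(wavelet)
    # map subband letters to array axes: axis_order 'xyz' means letter 0 -> x
    # which is array axis 2 (data is z,y,x)
    letter_to_axis = {"xyz": (2, 1, 0), "zyx": (0, 1, 2)}[axis_order]
    out = np.asarray(data, dtype=np.float64)
    for letter, axis in zip(subband, letter_to_axis):
        filt = hi if letter == "H" else lo
        out = correlate1d(out, filt, axis=axis, mode="reflect")
    return out


def wavelet_hlh(volume: ImageVolume, wavelet: str = "coif1",
                axis_order: str = "xyz") -> ImageVolume:
    """The HLH subband of a one-level undecimated coiflet-1 decomposition."""
    out = wavelet_subband(volume, "HLH", wavelet, axis_order)
    return ImageVolume(out, volume.spacing_mm, volume.origin_mm, volume.units)


def _whole_roi_features(data: np.ndarray, fg: np.ndarray,
                        config: FeatureConfig,
                        names: tuple[str, ...]) -> dict[str, float]:
    out: dict[str, float] = {}
    if "energy" in names or "entropy" in names:
        fo = first_order(data, fg, config.bin_width)
        for k in ("energy", "entropy"):
            if k in names:
                out[k] = fo[k]
    needs_levels = {"glcm_contrast", "glcm_dissimilarity", "glrlm_gln"} & set(names)
    if needs_levels:
        levels = discretize(data, fg, config.bin_width)
        if "glcm_contrast" in names or "glcm_dissimilarity" in names:
            g = glcm_features(levels, fg, config)
            for k in ("glcm_contrast", "glcm_dissimilarity"):
                if k in names:
                    out[k] = g[k]
        if "glrlm_gln" in names:
            out["glrlm_gln"] = glrlm_gln(levels, fg, config)
    if "wavelet_hlh_gln" in names:
        sub = wavelet_subband(data, "HLH", config.wavelet, config.wavelet_axis_order)
        wav_levels = discretize(sub, fg, config.bin_width)
        out["wavelet_hlh_gln"] = glrlm_gln(wav_levels, fg, config)
    return out


def patchwise_features(volume: ImageVolume, mask: SegmentationMask,
                       config: FeatureConfig,
                       names: tuple[str, ...] = FEATURE_NAMES) -> FeatureVector:
    """Tile the ROI bounding box into 2x2x2 mm patches and average features.

    Patch size in voxels is round(mm / spacing) per axis (minimum 1). Each
    feature is computed per patch over that patch's in-mask voxels; patches
    with under 50% mask coverage are skipped. The aggregate is the
    unweighted mean over contributing patches.
    """
    fg = mask.data > 0
    if not fg.any():
        raise ValueError("mask is empty")
    coords = np.argwhere(fg)
    lo, hi = coords.min(axis=0), coords.max(axis=0) + 1
    patch_vox = tuple(
        max(1, int(round(p / s)))
        for p, s in zip(config.patch_size_mm, volume.spacing_mm)
    )
    sums: dict[str, float] = {k: 0.0 for k in names}
    n_used = 0
    for z0 in range(lo[0], hi[0], patch_vox[0]):
        for y0 in range(lo[1], hi[1], patch_vox[1]):
            for x0 in range(lo[2], hi[2], patch_vox[2]):
                box = (slice(z0, min(z0 + patch_vox[0], hi[0])),
                       slice(y0, min(y0 + patch_vox[1], hi[1])),
                       slice(x0, min(x0 + patch_vox[2], hi[2])))
                sub_fg = fg[box]
                if sub_fg.mean() < config.min_patch_coverage:
                    continue
                if sub_fg.sum() < 2:
                    continue
                with warnings.catch_warnings():
                    # tiny patches routinely have pair-less directions
                    warnings.simplefilter("ignore", UserWarning)
                    vals = _whole_roi_features(volume.data[box], sub_fg, config, names)
                for k, v in vals.items():
                    sums[k] += v
                n_used += 1
    if n_used == 0:
        raise ValueError(
            f"no patch reached {config.min_patch_coverage:.0%} mask coverage"
        )
    return FeatureVector(
        values={k: sums[k] / n_used for k in names},
        config=config,
        roi_label="",
    )


def extract_feature_vector(volume: ImageVolume, mask: SegmentationMask,
                           config: FeatureConfig | None = None,
                           roi_label: str = "",
                           names: tuple[str, ...] = FEATURE_NAMES) -> FeatureVector:
    """Compute the six-feature prognostic panel for one ROI.

    Dispatches to the whole-ROI or patchwise path according to
    ``config.patchwise``; the configuration is recorded in the result.
    """
    config = config or FeatureConfig()
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share one grid")
    if config.patchwise:
        fv = patchwise_features(volume, mask, config, names)
        return replace(fv, roi_label=roi_label)
    try:
        values = _whole_roi_features(volume.data, mask.data > 0, config, names)
    except ValueError as exc:
        raise ValueError(f"feature extraction failed for ROI '{roi_label}': {exc}") from exc
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values for ROI '{roi_label}': {bad}")
    return FeatureVector(values=values, config=config, roi_label=roi_label)
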