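"""In-silico phantoms and scan-mode perturbations.

The physical phantom is a disc of two resins whose dithered mixture renders
a heterogeneous liver-like background (around 65–125 HU) with embedded
heterogeneous lesions. This module generates a digital stand-in — a
band-passed random texture inside a disc support with blob-shaped lesions
of distinct texture — plus repeat-scan noise and phenomenological analogues
of the clinical scan modes: quantum noise scaling with dose, smoothing for
iterative reconstruction (ASiR), unsharp sharpening for lung/bone kernels,
in-plane pixel-size changes for DFOV, and a linear shading field for
off-center positioning. These are image-domain emulations, not CT physics;
their job is to exercise the feature-extraction and QC statistics chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from phantomforge.phantom_design import disc_support_mask
from phantomforge.volume_io import ImageVolume, SegmentationMask, Units

BACKGROUND_RANGE_HU = (65.0, 125.0)  # the two printed resins' HU analogs
DEFAULT_NOISE_SIGMA_HU = 5.0


@dataclass(frozen=True)
class ScanModeSpec:
    """Phenomenological description of one scan mode.

    noise_sigma_hu
        Additive Gaussian noise amplitude before dose scaling.
    dose_scale
        Relative dose; effective noise is noise_sigma_hu / sqrt(dose_scale).
    smoothing_sigma_mm
        Gaussian smoothing (iterative-reconstruction analogue).
    kernel_boost
        Unsharp-mask gain (sharp lung/bone kernel analogue).
    pixel_size_mm
        In-plane resampling target (DFOV analogue); None keeps the grid.
    shading_gradient_hu_per_mm
        Linear in-plane shading (off-center bow-tie analogue).
    """

    name: str = "baseline"
    noise_sigma_hu: float = 0.0
    dose_scale: float = 1.0
    smoothing_sigma_mm: float = 0.0
    kernel_boost: float = 0.0
    pixel_size_mm: float | None = None
    shading_gradient_hu_per_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")
        if self.dose_scale <= 0:
            raise ValueError("dose_scale must be positive")
        if self.smoothing_sigma_mm < 0 or self.kernel_boost < 0:
            raise ValueError("smoothing and kernel boost must be >= 0")
        if self.pixel_size_mm is not None and self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")


# Presets mirror the clinical scan-mode list: iterative-reconstruction
# strengths, sharp kernels, reduced tube current/potential, off-center
# placement, enlarged display field of view, and a dual-energy analogue.
# Magnitudes are simulator choices preserving the qualitative orderings
# (more ASiR -> smoother; less dose -> noisier).
SCAN_MODE_PRESETS: dict[str, ScanModeSpec] = {
    "baseline": ScanModeSpec("baseline"),
    "asir10": ScanModeSpec("asir10", smoothing_sigma_mm=0.3),
    "asir20": ScanModeSpec("asir20", smoothing_sigma_mm=0.5),
    "asir30": ScanModeSpec("asir30", smoothing_sigma_mm=0.7),
    "lung": ScanModeSpec("lung", kernel_boost=1.0, noise_sigma_hu=3.0),
    "lung_asir40": ScanModeSpec("lung_asir40", kernel_boost=1.0,
                                smoothing_sigma_mm=0.9, noise_sigma_hu=3.0),
    "bone": ScanModeSpec("bone", kernel_boost=1.5, noise_sigma_hu=4.0),
    "ma100": ScanModeSpec("ma100", noise_sigma_hu=5.0, dose_scale=100 / 280),
    "kvp100": ScanModeSpec("kvp100", noise_sigma_hu=5.0, dose_scale=0.5),
    "offcenter30": ScanModeSpec("offcenter30", noise_sigma_hu=2.0,
                                shading_gradient_hu_per_mm=0.15),
    "dfov350": ScanModeSpec("dfov350", pixel_size_mm=0.684),
    "dect60": ScanModeSpec("dect60", noise_sigma_hu=4.0,
                           smoothing_sigma_mm=0.4, kernel_boost=0.3),
}


@dataclass
class DigitalPhantom:
    """A textured disc with embedded lesions, all reproducible from a seed."""

    volume: ImageVolume
    lesion_masks: list[SegmentationMask] = field(default_factory=list)
    background_mask: SegmentationMask | None = None
    seed: int = 0


def _bandpassed_texture(rng: np.random.Generator, shape: tuple[int, int, int],
                        sigma_fine: float, sigma_coarse: float) -> np.ndarray:
    """Zero-mean band-passed Gaussian noise, unit-ish amplitude."""
    noise = rng.standard_normal(shape)
    band = (ndimage.gaussian_filter(noise, sigma_fine)
            - ndimage.gaussian_filter(noise, sigma_coarse))
    band -= band.mean()
    scale = np.abs(band).max()
    return band / scale if scale > 0 else band


def _blob_mask(rng: np.random.Generator, shape: tuple[int, int, int],
               center: np.ndarray, base_radius_vox: float,
               wobble: float = 0.12) -> np.ndarray:
    """Sphere with a smooth random radial perturbation (a lesion-like blob).

    The wobble is bounded, so the blob radius stays within
    (1 +- wobble) * base_radius. Computed in a local bounding box.
    """
    pad = int(np.ceil(base_radius_vox * (1 + wobble))) + 2
    lo = [max(0, int(np.floor(c)) - pad) for c in center]
    hi = [min(n, int(np.ceil(c)) + pad + 1) for c, n in zip(center, shape)]
    box_shape = tuple(h - l for l, h in zip(lo, hi))
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    # low-frequency multiplicative wobble of the radius
    pert = ndimage.gaussian_filter(rng.standard_normal(box_shape), 6.0)
    pmax = np.abs(pert).max()
    if pmax > 0:
        pert = pert / pmax * wobble
    out = np.zeros(shape, dtype=bool)
    out[tuple(slice(l, h) for l, h in zip(lo, hi))] = (
        r <= base_radius_vox * (1.0 + pert)
    )
    return out


def generate_digital_phantom(seed: int = 42, n_lesions: int = 5,
                             extent_vox: tuple[int, int, int] = (64, 192, 192),
                             spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                             min_lesion_vox: int = 32**3,
                             max_retries: int = 200) -> DigitalPhantom:
    """Generate a heterogeneous disc phantom with blob lesions.

    The background is band-passed random texture scaled into the printed
    resins' HU range [65, 125] inside an inscribed disc support. Lesions
    are blob-shaped regions with their own (coarser, compressed-range)
    texture, each at least ``min_lesion_vox`` voxels, mutually disjoint and
    away from the disc rim. Lesion centers sit on a jittered ring (the
    physical phantom's tumor placement was arbitrary; a ring keeps large
    lesions apart by construction). Deterministic for a fixed
    (seed, geometry).
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in extent_vox)
    lo_hu, hi_hu = BACKGROUND_RANGE_HU

    texture = _bandpassed_texture(rng, shape, sigma_fine=1.0, sigma_coarse=4.0)
    background = lo_hu + (texture - texture.min()) / np.ptp(texture) * (hi_hu - lo_hu)

    disc_r_mm = min(shape[1] * spacing_mm[1], shape[2] * spacing_mm[2]) / 2
    support = disc_support_mask(
        shape, spacing_mm,
        diameter_mm=2 * disc_r_mm,
        thickness_mm=shape[0] * spacing_mm[0],
    ).astype(bool)

    # blob radius sized so even the maximally shrunk blob clears the floor
    wobble = 0.12
    base_radius = (min_lesion_vox * 3 / (4 * np.pi)) ** (1 / 3) / (1 - wobble) * 1.02
    max_radius = base_radius * (1 + wobble)

    lesion_masks: list[np.ndarray] = []
    claimed = np.zeros(shape, dtype=bool)
    ring_r_vox = 0.58 * disc_r_mm / max(spacing_mm[1:])
    cz_mid = (shape[0] - 1) / 2
    cz_half = max(0.0, cz_mid - max_radius - 2)
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(n_lesions):
        placed = False
        for _ in range(max_retries):
            angle = phase + 2 * np.pi * k / max(n_lesions, 1) + rng.uniform(-0.05, 0.05)
            rr = ring_r_vox + rng.uniform(-3.0, 3.0)
            center = np.array([
                cz_mid + rng.uniform(-cz_half, cz_half),
                (shape[1] - 1) / 2 + rr * np.sin(angle),
                (shape[2] - 1) / 2 + rr * np.cos(angle),
            ])
            # the whole blob must fit inside the grid and the disc rim
            if np.hypot(center[1] - (shape[1] - 1) / 2,
                        center[2] - (shape[2] - 1) / 2) + max_radius > disc_r_mm - 1:
                continue
            if (center - max_radius < 0).any() or (
                    center + max_radius > np.array(shape) - 1).any():
                continue
            blob = _blob_mask(rng, shape, center, base_radius, wobble)
            if (blob & claimed).any() or blob.sum() < min_lesion_vox:
                continue
            claimed |= blob
            lesion_masks.append(blob)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {k + 1}/{n_lesions} without overlap "
                f"after {max_retries} attempts"
            )

    data = background.copy()
    for blob in lesion_masks:
        # Each printed tumor was normalized on its own to the full material
        # ratio range, so a lesion spans the whole resin HU band with a
        # broad histogram. Emulated as a structure + fine-scale random
        # mixture (anatomy plus the patient-image noise baked into the
        # print), rank-mapped to a uniform histogram over [65, 125].
        struct = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
        fine = ndimage.gaussian_filter(rng.standard_normal(shape), 0.6)
        tex = 0.6 * struct / struct.std() + 0.4 * fine / fine.std()
        inside = tex[blob]
        ranks = np.argsort(np.argsort(inside)) + 0.5
        data[blob] = lo_hu + ranks / inside.size * (hi_hu - lo_hu)
    data[~support] = 0.0

    vol = ImageVolume(data, spacing_mm, units=Units.HU)
    bg_mask = support & ~claimed
    return DigitalPhantom(
        volume=vol,
        lesion_masks=[SegmentationMask(m & support, spacing_mm) for m in lesion_masks],
        background_mask=SegmentationMask(bg_mask, spacing_mm),
        seed=seed,
    )


def simulate_repeat_scans(phantom: DigitalPhantom, n: int = 30,
                          noise_sigma_hu: float = DEFAULT_NOISE_SIGMA_HU,
                          seed: int = 0,
                          correlation_sigma_vox: float = 0.0) -> list[ImageVolume]:
    """Repeat scans = phantom + independent Gaussian noise per replicate.

    Optionally the noise field is smoothed (``correlation_sigma_vox``) to
    mimic spatially correlated reconstruction noise; the field is rescaled
    so its per-voxel SD stays ``noise_sigma_hu``. Replicate streams are
    independent but reproducible for a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 repeat scans")
    if noise_sigma_hu < 0:
        raise ValueError("noise sigma must be >= 0")
    base = phantom.volume.data
    streams = np.random.default_rng(seed).spawn(n)
    out = []
    for rng in streams:
        noise = rng.standard_normal(base.shape)
        if correlation_sigma_vox > 0:
            noise = ndimage.gaussian_filter(noise, correlation_sigma_vox)
            noise /= noise.std()
        out.append(phantom.volume.with_data(base + noise_sigma_hu * noise))
    return out


def apply_scan_mode(volume: ImageVolume, mode: ScanModeSpec,
                    seed: int = 0) -> ImageVolume:
    """Apply a scan mode's perturbation chain to one volume.

    Order: dose-scaled noise, Gaussian smoothing, unsharp-mask boost,
    in-plane resampling, linear shading. Stages with neutral parameters are
    skipped, so the all-neutral baseline is an exact identity.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    spacing = list(volume.spacing_mm)
    changed = False

    sigma_eff = mode.noise_sigma_hu / np.sqrt(mode.dose_scale)
    if sigma_eff > 0:
        rng = np.random.default_rng(seed)
        data = data + sigma_eff * rng.standard_normal(data.shape)
        changed = True
    if mode.smoothing_sigma_mm > 0:
        sig_vox = [mode.smoothing_sigma_mm / s for s in spacing]
        data = ndimage.gaussian_filter(data, sig_vox)
        changed = True
    if mode.kernel_boost > 0:
        blurred = ndimage.gaussian_filter(data, 1.0)
        data = data + mode.kernel_boost * (data - blurred)
        changed = True
    if mode.pixel_size_mm is not None and any(
            abs(mode.pixel_size_mm - s) > 1e-9 for s in spacing[1:]):
        zoom = (1.0, spacing[1] / mode.pixel_size_mm, spacing[2] / mode.pixel_size_mm)
        data = ndimage.zoom(data, zoom, order=1)
        spacing[1] = spacing[2] = mode.pixel_size_mm
        changed = True
    if mode.shading_gradient_hu_per_mm != 0:
        ny = data.shape[1]
        y_mm = (np.arange(ny) - (ny - 1) / 2) * spacing[1]
        data = data + mode.shading_gradient_hu_per_mm * y_mm[None, :, None]
        changed = True

    if not changed:
        return volume
    return ImageVolume(data, tuple(spacing), volume.origin_mm, volume.units)


def dfov_pixel_size(dfov_mm: float, matrix: int = 512) -> float:
    """Reconstructed in-plane pixel size: DFOV / matrix, to 3 decimals (mm)."""
    if dfov_mm <= 0:
        raise ValueError("dfov_mm must be positive")
    if matrix < 1:
        raise ValueError("matrix must be >= 1")
    return round(dfov_mm / matrix, 3)
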