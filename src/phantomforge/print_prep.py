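"""Print preparation: supersampling, error-diffusion dithering, material stacks.

The designed mix-ratio volume is supersampled to the printer's droplet grid
with Whittaker–Shannon (sinc) interpolation, sliced into layers, and each
layer binarized with Floyd–Steinberg error diffusion. The binarized layer is
the deposition map of the high-attenuation resin; the second resin's bitmaps
are its bitwise inversion within the part, and the third channel is all
zeros — two materials of opposing attenuation are enough to render the
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from phantomforge.volume_io import (
    CHANNELS,
    ImageVolume,
    RasterStack,
    SegmentationMask,
    Units,
)


@dataclass(frozen=True)
class PrinterSpec:
    """Geometry of the multimaterial voxel printer.

    Defaults correspond to a droplet pitch of 48 x 84 um in-plane (x, y)
    and 30 um layers, on a build tray of 255 x 252 x 200 mm (x, y, z).
    """

    dot_pitch_mm: tuple[float, float] = (0.084, 0.048)  # (y, x)
    layer_thickness_mm: float = 0.030
    build_extent_mm: tuple[float, float, float] = (200.0, 252.0, 255.0)  # (z, y, x)

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.dot_pitch_mm) or self.layer_thickness_mm <= 0:
            raise ValueError("printer pitch and layer thickness must be positive")

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return (self.layer_thickness_mm, *self.dot_pitch_mm)


@dataclass(frozen=True)
class MixRatioVolume:
    """Mix-ratio volume at printer resolution plus its part-support mask."""

    volume: ImageVolume
    support: SegmentationMask

    def __post_init__(self) -> None:
        if self.volume.units is not Units.RATIO:
            raise ValueError("mix ratio volume must carry RATIO units")
        if self.volume.shape != self.support.shape:
            raise ValueError("support mask must share the volume grid")


# ---------------------------------------------------------------------------
# Whittaker–Shannon supersampling


def _is_integer_factor(src: float, dst: float, tol: float = 1e-9) -> int | None:
    f = src / dst
    r = round(f)
    return r if r >= 1 and abs(f - r) < tol * max(1.0, f) else None


def _fft_supersample_axis(data: np.ndarray, axis: int, factor: int) -> np.ndarray:
    """Exact band-limited (periodic) sinc interpolation by FFT zero-padding.

    Output samples are voxel-center aligned: fine voxel centers tile the
    same field of view, so fine sample j sits at (j + 1/2)/factor - 1/2 in
    source-sample coordinates (applied as a linear phase).
    """
    n = data.shape[axis]
    m = n * factor
    spec = np.fft.fft(data, axis=axis)
    spec = np.fft.fftshift(spec, axes=axis)
    pad_lo = (m - n) // 2
    pad_hi = m - n - pad_lo
    pad = [(0, 0)] * data.ndim
    pad[axis] = (pad_lo, pad_hi)
    spec = np.pad(spec, pad)
    # split the (even-n) Nyquist bin symmetrically to keep the result real
    if n % 2 == 0:
        idx_lo = [slice(None)] * data.ndim
        idx_lo[axis] = slice(pad_lo, pad_lo + 1)
        idx_hi = list(idx_lo)
        idx_hi[axis] = slice(pad_lo + n, pad_lo + n + 1)
        nyq = spec[tuple(idx_lo)] / 2
        spec[tuple(idx_lo)] = nyq
        spec[tuple(idx_hi)] = nyq
    spec = np.fft.ifftshift(spec, axes=axis)
    # voxel-center shift, in source-sample units (period n)
    x0 = (1.0 / factor - 1.0) / 2.0
    freqs = np.fft.fftfreq(m, d=1.0 / factor)  # cycles per source sample
    phase = np.exp(2j * np.pi * freqs * x0)
    shape = [1] * data.ndim
    shape[axis] = m
    spec = spec * phase.reshape(shape)
    out = np.fft.ifft(spec, axis=axis).real * factor
    return out


def _lanczos3_resample_axis(data: np.ndarray, axis: int, src_sp: float,
                            dst_sp: float) -> np.ndarray:
    """Windowed-sinc (Lanczos a=3) interpolation for non-integer factors."""
    a = 3
    n = data.shape[axis]
    # voxel-center alignment: both grids span the same physical field of view
    extent = n * src_sp
    m = int(round(extent / dst_sp))
    # target center positions in source-sample coordinates
    t = ((np.arange(m) + 0.5) * dst_sp) / src_sp - 0.5
    base = np.floor(t).astype(int)
    weights = np.zeros((m, 2 * a))
    idx = np.zeros((m, 2 * a), dtype=int)
    for k in range(-a + 1, a + 1):
        j = base + k
        x = t - j
        w = np.sinc(x) * np.sinc(x / a) * (np.abs(x) < a)
        idx[:, k + a - 1] = np.clip(j, 0, n - 1)  # edge replication
        weights[:, k + a - 1] = w
    weights /= weights.sum(axis=1, keepdims=True)
    moved = np.moveaxis(data, axis, -1)
    gathered = moved[..., idx]          # (..., m, 2a)
    out = (gathered * weights).sum(axis=-1)
    return np.moveaxis(out, -1, axis)


def sinc_resample(volume: ImageVolume,
                  target_spacing_mm: tuple[float, float, float]) -> ImageVolume:
    """Supersample a volume to a finer grid by sinc interpolation.

    Integer upsampling factors use exact FFT zero-padding (periodic
    Whittaker–Shannon interpolation); non-integer factors fall back to a
    Lanczos-3 windowed sinc. Target spacing must not be coarser than the
    source on any axis — downsampling is out of contract.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(t > s * (1 + 1e-9) for t, s in zip(target, volume.spacing_mm)):
        raise ValueError(
            f"target spacing {target} is coarser than source "
            f"{volume.spacing_mm}; only supersampling is supported"
        )
    data = np.asarray(volume.data, dtype=np.float64)
    origin = list(volume.origin_mm)
    for axis in range(3):
        src, dst = volume.spacing_mm[axis], target[axis]
        if abs(src - dst) < 1e-12:
            continue
        factor = _is_integer_factor(src, dst)
        if factor is not None:
            data = _fft_supersample_axis(data, axis, factor)
        else:
            data = _lanczos3_resample_axis(data, axis, src, dst)
        origin[axis] += (dst - src) / 2  # first fine voxel center
    if volume.units is Units.RATIO:
        data = np.clip(data, 0.0, 1.0)  # ringing may slightly overshoot
    return ImageVolume(data, target, tuple(origin), volume.units)


# ---------------------------------------------------------------------------
# Floyd–Steinberg dithering

# error-diffusion weights to (right, down-left, down, down-right)
_FS_WEIGHTS = ((0, 1, 7 / 16), (1, -1, 3 / 16), (1, 0, 5 / 16), (1, 1, 1 / 16))


def dither_slice(slice2d: np.ndarray) -> np.ndarray:
    """Binarize a [0, 1] slice with Floyd–Steinberg error diffusion.

    Fixed raster (non-serpentine) scan order, threshold 0.5, classic
    7/16, 3/16, 5/16, 1/16 weights. At the slice border the weights of the
    remaining in-bounds neighbors are renormalized to sum to one, so
    quantization error is never lost off the edge and the slice mean is
    conserved to within the final pixel's residual (< 1 gray level over the
    whole slice). Deterministic: identical input gives an identical bitmap.
    """
    work = np.asarray(slice2d, dtype=np.float64).copy()
    if work.ndim != 2:
        raise ValueError("dither_slice expects a 2D array")
    if work.size and (work.min() < -1e-12 or work.max() > 1 + 1e-12):
        raise ValueError(
            f"slice values must lie in [0,1]; got [{work.min()}, {work.max()}]"
        )
    ny, nx = work.shape
    out = np.zeros((ny, nx), dtype=np.uint8)
    for y in range(ny):
        row = work[y]
        below = work[y + 1] if y + 1 < ny else None
        for x in range(nx):
            old = row[x]
            new = 1.0 if old >= 0.5 else 0.0
            out[y, x] = new
            err = old - new
            has_right = x + 1 < nx
            has_left = x - 1 >= 0
            total = 0.0
            if has_right:
                total += 7 / 16
            if below is not None:
                total += 5 / 16
                if has_left:
                    total += 3 / 16
                if has_right:
                    total += 1 / 16
            if total == 0.0:
                continue  # bottom-right corner: no unprocessed neighbor
            scale = err / total
            if has_right:
                row[x + 1] += scale * (7 / 16)
            if below is not None:
                if has_left:
                    below[x - 1] += scale * (3 / 16)
                below[x] += scale * (5 / 16)
                if has_right:
                    below[x + 1] += scale * (1 / 16)
    return out


def build_material_stacks(mix: MixRatioVolume, spec: PrinterSpec,
                          one_is_high_attenuation: bool = True) -> RasterStack:
    """Dither a mix-ratio volume layer by layer into three material stacks.

    Channel A carries the dithered bitmap, channel B its inversion within the
    part support, and channel C is all zeros. With the default orientation a
    bitmap value of 1 deposits the high-attenuation resin (mix ratio 1 is the
    brightest tissue); set ``one_is_high_attenuation=False`` to swap the two
    active resins. Outside the support no channel deposits material.
    """
    if any(abs(a - b) > 1e-6 for a, b in zip(mix.volume.spacing_mm, spec.spacing_mm)):
        raise ValueError(
            f"mix volume spacing {mix.volume.spacing_mm} does not match "
            f"printer spacing {spec.spacing_mm}"
        )
    support = mix.support.data.astype(bool)
    nz = mix.volume.shape[0]
    a_planes = []
    for z in range(nz):
        bitmap = dither_slice(mix.volume.data[z])
        bitmap[~support[z]] = 0
        a_planes.append(bitmap)
    a = np.stack(a_planes, axis=0)
    b = (support & (a == 0)).astype(np.uint8)
    if not one_is_high_attenuation:
        a, b = b, a
    c = np.zeros_like(a)
    return RasterStack(
        channels={"A": a, "B": b, "C": c},
        dot_pitch_mm=spec.dot_pitch_mm,
        layer_thickness_mm=spec.layer_thickness_mm,
    )


def rasterize_design(mix_volume: ImageVolume, support: SegmentationMask,
                     spec: PrinterSpec) -> RasterStack:
    """Supersample a RATIO design to printer resolution and dither it."""
    fine = sinc_resample(mix_volume, spec.spacing_mm)
    sup = sinc_resample(
        ImageVolume(support.data.astype(np.float64), support.spacing_mm,
                    support.origin_mm, Units.RATIO),
        spec.spacing_mm,
    )
    fine_support = SegmentationMask(
        (sup.data >= 0.5).astype(np.uint8), fine.spacing_mm, fine.origin_mm
    )
    return build_material_stacks(MixRatioVolume(fine, fine_support), spec)
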