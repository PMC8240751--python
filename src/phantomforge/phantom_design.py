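"""Phantom design: ROI extraction, normalization, compositing, disc layout.

Tumor ROIs are cut out of a source scan at their mask bounding box, each one
min–max normalized over its own in-mask voxels to a material mix ratio in
[0, 1], and composited into a heterogeneous background. The finished design
is a disc (default 180 mm diameter x 40 mm thick) whose out-of-support
voxels carry mix ratio 0 so no resin is deposited outside the part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from phantomforge.volume_io import ImageVolume, SegmentationMask, Units


@dataclass(frozen=True)
class ROIPatch:
    """A tumor (or background sample) cropped to its mask bounding box."""

    volume: ImageVolume
    mask: SegmentationMask
    label: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.volume.shape != self.mask.shape:
            raise ValueError("ROI volume and mask must share one grid")
        if self.mask.n_foreground == 0:
            raise ValueError("ROI mask has no foreground voxels")


@dataclass(frozen=True)
class Placement:
    """Integer voxel offset of an ROI's bounding-box corner in the background."""

    roi_label: str
    offset_vox: tuple[int, int, int]


@dataclass
class PhantomDesign:
    """Digital twin of the printed disc: background, placed ROIs, geometry."""

    background: ImageVolume
    rois: list[ROIPatch] = field(default_factory=list)
    placements: list[Placement] = field(default_factory=list)
    disc_diameter_mm: float = 180.0
    disc_thickness_mm: float = 40.0
    support: SegmentationMask | None = None

    def __post_init__(self) -> None:
        if self.disc_diameter_mm <= 0 or self.disc_thickness_mm <= 0:
            raise ValueError("disc dimensions must be positive")


def extract_roi(volume: ImageVolume, mask: SegmentationMask, label: str,
                source_id: str = "") -> ROIPatch:
    """Crop ``volume`` and ``mask`` to the tight bounding box of the mask.

    Voxel values inside the crop are carried over unchanged.
    """
    if mask.shape != volume.shape:
        raise ValueError("mask and volume must share one grid")
    fg = np.argwhere(mask.data > 0)
    if fg.size == 0:
        raise ValueError("cannot extract an ROI from an empty mask")
    lo = fg.min(axis=0)
    hi = fg.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = tuple(
        o + int(a) * s
        for o, a, s in zip(volume.origin_mm, lo, volume.spacing_mm)
    )
    sub = ImageVolume(volume.data[box].copy(), volume.spacing_mm, origin, volume.units)
    sub_mask = SegmentationMask(mask.data[box].copy(), volume.spacing_mm, origin)
    return ROIPatch(sub, sub_mask, label=label, source_id=source_id)


def normalize_unit(patch: ROIPatch) -> ROIPatch:
    """Min–max normalize the in-mask voxels of a patch to [0, 1].

    The map is (v - min) / (max - min) over in-mask voxels only; out-of-mask
    voxels are set to 0. A constant patch has no defined range and falls back
    to mix ratio 0.5 everywhere in-mask, with a warning.
    """
    fg = patch.mask.data > 0
    values = patch.volume.data[fg].astype(np.float64)
    out = np.zeros(patch.volume.shape, dtype=np.float64)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        warnings.warn(
            f"ROI '{patch.label}' is constant (value {vmin}); "
            "assigning mid-mixture ratio 0.5",
            stacklevel=2,
        )
        out[fg] = 0.5
    else:
        out[fg] = (patch.volume.data[fg] - vmin) / (vmax - vmin)
    vol = ImageVolume(out, patch.volume.spacing_mm, patch.volume.origin_mm, Units.RATIO)
    return ROIPatch(vol, patch.mask, label=patch.label, source_id=patch.source_id)


def composite(background: ImageVolume, rois: list[ROIPatch],
              placements: list[Placement]) -> ImageVolume:
    """Replace background voxels with ROI values inside each placed mask.

    Outside all masks the background is returned bit-for-bit unchanged.
    Placements must fit inside the background and their masks must not
    overlap.
    """
    by_label = {r.label: r for r in rois}
    out = np.array(background.data, copy=True)
    claimed = np.zeros(background.shape, dtype=bool)
    for pl in placements:
        roi = by_label.get(pl.roi_label)
        if roi is None:
            raise ValueError(f"no ROI with label '{pl.roi_label}'")
        if roi.volume.units != background.units:
            raise ValueError(
                f"units mismatch: ROI '{roi.label}' is {roi.volume.units.value}, "
                f"background is {background.units.value}"
            )
        off = tuple(int(v) for v in pl.offset_vox)
        if any(o < 0 or o + s > b for o, s, b in
               zip(off, roi.volume.shape, background.shape)):
            raise ValueError(
                f"placement of '{pl.roi_label}' at {off} exceeds background "
                f"extent {background.shape}"
            )
        box = tuple(slice(o, o + s) for o, s in zip(off, roi.volume.shape))
        fg = roi.mask.data > 0
        if (claimed[box] & fg).any():
            raise ValueError(f"placement of '{pl.roi_label}' overlaps a prior ROI")
        claimed[box] |= fg
        region = out[box]
        region[fg] = roi.volume.data[fg]
    return background.with_data(out)


def disc_support_mask(shape: tuple[int, int, int],
                      spacing_mm: tuple[float, float, float],
                      diameter_mm: float, thickness_mm: float) -> np.ndarray:
    """Binary in-part mask of an axis-aligned cylinder centered in the grid."""
    nz, ny, nx = shape
    dz, dy, dx = spacing_mm
    z = (np.arange(nz) - (nz - 1) / 2) * dz
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    in_height = np.abs(z) <= thickness_mm / 2
    r2 = (y[:, None] ** 2 + x[None, :] ** 2)
    in_disc = r2 <= (diameter_mm / 2) ** 2
    return (in_height[:, None, None] & in_disc[None, :, :]).astype(np.uint8)


def make_disc_design(background_texture: ImageVolume,
                     rois: list[ROIPatch] | None = None,
                     placements: list[Placement] | None = None,
                     diameter_mm: float = 180.0,
                     thickness_mm: float = 40.0) -> PhantomDesign:
    """Composite ROIs into the background and cut the result to a disc.

    The background texture must cover the disc extent. Voxels outside the
    inscribed cylinder get mix ratio 0 (RATIO designs) and are flagged
    out-of-support, so downstream rasterization deposits no material there.
    """
    rois = rois or []
    placements = placements or []
    extent = tuple(n * s for n, s in
                   zip(background_texture.shape, background_texture.spacing_mm))
    if extent[0] < thickness_mm or min(extent[1], extent[2]) < diameter_mm:
        raise ValueError(
            f"background extent {extent} mm cannot cover a "
            f"{diameter_mm} x {thickness_mm} mm disc"
        )
    merged = composite(background_texture, rois, placements)
    support = disc_support_mask(merged.shape, merged.spacing_mm,
                                diameter_mm, thickness_mm)
    data = np.array(merged.data, copy=True)
    data[support == 0] = 0
    vol = merged.with_data(data)
    return PhantomDesign(
        background=vol,
        rois=rois,
        placements=placements,
        disc_diameter_mm=diameter_mm,
        disc_thickness_mm=thickness_mm,
        support=SegmentationMask(support, merged.spacing_mm, merged.origin_mm),
    )
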