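"""Image and raster I/O.

Every reader converts into one internal convention: arrays are indexed
``(z, y, x)``, spacing/origin tuples follow the same axis order, and CT
intensities are Hounsfield units after slope/intercept rescale. Raster
stacks — the printer-facing product — are written as 1-bit PNGs, one file
per (layer, material channel), with a JSON manifest.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image


class Units(str, Enum):
    """Intensity unit tag carried by every :class:`ImageVolume`."""

    HU = "HU"          # Hounsfield units
    RATIO = "RATIO"    # material mix ratio in [0, 1]
    LEVELS = "LEVELS"  # discretized gray levels (positive integers)


class GridMismatchError(ValueError):
    """Mask or volume does not live on the expected voxel grid."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values, axis order (z, y, x).
    spacing_mm : tuple of float
        Voxel spacing per axis (z, y, x), strictly positive, in mm.
    origin_mm : tuple of float
        Physical position of voxel (0, 0, 0), in mm.
    units : Units
        Intensity unit tag. RATIO volumes must lie in [0, 1].
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: Units = Units.HU

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        units = Units(self.units)
        object.__setattr__(self, "units", units)
        if units is Units.RATIO:
            lo, hi = float(data.min()), float(data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(f"RATIO volume values must lie in [0,1]; got [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def with_data(self, data: np.ndarray, units: Units | None = None) -> "ImageVolume":
        """Same grid, new voxel values (and optionally a new unit tag)."""
        return ImageVolume(data, self.spacing_mm, self.origin_mm,
                           self.units if units is None else units)


@dataclass(frozen=True)
class SegmentationMask:
    """Binary mask on the grid of a reference :class:`ImageVolume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={data.ndim}")
        object.__setattr__(self, "data", (data != 0).astype(np.uint8))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


CHANNELS = ("A", "B", "C")


@dataclass
class RasterStack:
    """Per-layer 1-bit bitmaps for the three printer material channels.

    ``channels[name]`` is a (n_layers, ny, nx) binary array. Within the
    printed part exactly one of the two active resins is deposited per dot
    (A + B == 1) and the third channel is all zeros.
    """

    channels: dict[str, np.ndarray]
    dot_pitch_mm: tuple[float, float]      # (y, x)
    layer_thickness_mm: float
    layers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNELS):
            raise ValueError(f"channels must be exactly {CHANNELS}")
        shapes = {self.channels[c].shape for c in CHANNELS}
        if len(shapes) != 1:
            raise ValueError("all channel bitmaps must share one shape")
        for c in CHANNELS:
            arr = np.asarray(self.channels[c])
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"channel {c} bitmap is not binary")
            self.channels[c] = arr.astype(np.uint8)
        if not self.layers:
            self.layers = list(range(self.channels["A"].shape[0]))

    @property
    def n_layers(self) -> int:
        return self.channels["A"].shape[0]


# ---------------------------------------------------------------------------
# DICOM intake


def read_dicom_series(directory: str | Path) -> ImageVolume:
    """Read a single-frame CT series into an HU volume.

    Slices are sorted by their position along the slice normal (not by
    filename), stored values are mapped to HU with the per-slice rescale
    slope/intercept, and spacing is taken from PixelSpacing plus the median
    inter-slice distance.

    Raises
    ------
    ValueError
        On an empty directory, mixed SeriesInstanceUIDs, or inconsistent
        in-plane matrix sizes.
    """
    directory = Path(directory)
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM image slices found in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"mixed series in {directory}: {sorted(map(str, uids))}")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent in-plane dimensions: {sorted(shapes)}")

    def slice_location(ds) -> float:
        # project ImagePositionPatient onto the slice normal
        ipp = np.asarray(getattr(ds, "ImagePositionPatient", (0.0, 0.0, 0.0)), float)
        iop = np.asarray(
            getattr(ds, "ImageOrientationPatient", (1, 0, 0, 0, 1, 0)), float
        )
        normal = np.cross(iop[:3], iop[3:])
        return float(ipp @ normal)

    datasets.sort(key=slice_location)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    data = np.stack(slices, axis=0)
    if np.allclose(data, np.round(data)):
        data = np.round(data).astype(np.int32)

    py, px = (float(v) for v in datasets[0].PixelSpacing)
    locs = [slice_location(ds) for ds in datasets]
    if len(locs) > 1:
        dz = float(np.median(np.diff(locs)))
        if dz <= 0:
            dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    ipp0 = getattr(datasets[0], "ImagePositionPatient", (0.0, 0.0, 0.0))
    origin = (float(locs[0]), float(ipp0[1]), float(ipp0[0]))
    return ImageVolume(data, (dz, py, px), origin, Units.HU)


# ---------------------------------------------------------------------------
# NIfTI / NRRD volumes


def _sitk():
    import SimpleITK as sitk  # deferred: not every code path needs it

    return sitk


_NIFTI_RE = re.compile(r"\.nii(\.gz)?$", re.IGNORECASE)


def read_volume(path: str | Path, units: Units = Units.HU) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume."""
    path = Path(path)
    if _NIFTI_RE.search(path.name):
        import nibabel as nib

        img = nib.load(str(path))
        # nibabel data axes are (x, y, z); flip to (z, y, x)
        data = np.asarray(img.dataobj).T
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        affine = img.affine
        origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
        return ImageVolume(data, spacing, origin, units)
    if path.suffix.lower() == ".nrrd":
        sitk = _sitk()
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        sp = img.GetSpacing()               # (x, y, z)
        og = img.GetOrigin()
        return ImageVolume(data, (sp[2], sp[1], sp[0]), (og[2], og[1], og[0]), units)
    raise ValueError(f"unsupported volume format: {path.name}")


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write to NIfTI or NRRD, preserving spacing and origin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _NIFTI_RE.search(path.name):
        import nibabel as nib

        affine = np.diag(list(volume.spacing_mm[::-1]) + [1.0])
        affine[0, 3], affine[1, 3], affine[2, 3] = volume.origin_mm[::-1]
        img = nib.Nifti1Image(np.asarray(volume.data).T, affine)
        img.header.set_zooms(volume.spacing_mm[::-1])
        nib.save(img, str(path))
        return
    if path.suffix.lower() == ".nrrd":
        sitk = _sitk()
        img = sitk.GetImageFromArray(np.asarray(volume.data))
        img.SetSpacing(tuple(volume.spacing_mm[::-1]))
        img.SetOrigin(tuple(volume.origin_mm[::-1]))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


def read_write_volume(volume: ImageVolume, path: str | Path) -> ImageVolume:
    """Round-trip a volume through disk (write then read back)."""
    write_volume(volume, path)
    return read_volume(path, units=volume.units)


GRID_TOL_MM = 1e-3  # absorbs format rounding in spacing/origin


def read_mask(path: str | Path, reference: ImageVolume) -> SegmentationMask:
    """Read a NIfTI/NRRD label image as a binary mask on ``reference``'s grid.

    Any nonzero label is foreground. The mask grid must match the reference
    shape exactly and its spacing/origin to within 1e-3 mm.
    """
    vol = read_volume(path, units=Units.LEVELS)
    if vol.shape != reference.shape:
        raise GridMismatchError(
            f"mask shape {vol.shape} != reference shape {reference.shape}"
        )
    for name, a, b in (("spacing", vol.spacing_mm, reference.spacing_mm),
                       ("origin", vol.origin_mm, reference.origin_mm)):
        if any(abs(x - y) > GRID_TOL_MM for x, y in zip(a, b)):
            raise GridMismatchError(f"mask {name} {a} != reference {name} {b}")
    return SegmentationMask(vol.data, reference.spacing_mm, reference.origin_mm)


# ---------------------------------------------------------------------------
# Raster stacks


def write_raster_stack(stack: RasterStack, directory: str | Path) -> dict:
    """Write one 1-bit PNG per (layer, channel) plus a JSON manifest.

    Files are named ``layer_{index:04d}_mat{A|B|C}.png``. Returns the
    manifest (also written to ``manifest.json``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_files = 0
    for i, layer in enumerate(stack.layers):
        for ch in CHANNELS:
            bitmap = stack.channels[ch][i]
            img = Image.fromarray((bitmap * 255).astype(np.uint8)).convert("1")
            img.save(directory / f"layer_{layer:04d}_mat{ch}.png")
            n_files += 1
    manifest = {
        "n_files": n_files,
        "n_layers": stack.n_layers,
        "channels": list(CHANNELS),
        "dot_pitch_mm": list(stack.dot_pitch_mm),
        "layer_thickness_mm": stack.layer_thickness_mm,
        "bitmap_shape": list(stack.channels["A"].shape[1:]),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_raster_stack(directory: str | Path) -> RasterStack:
    """Read back a stack written by :func:`write_raster_stack`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    layer_files = sorted(directory.glob("layer_*_matA.png"))
    layers = [int(p.name.split("_")[1]) for p in layer_files]
    channels = {}
    for ch in CHANNELS:
        planes = []
        for layer in layers:
            img = Image.open(directory / f"layer_{layer:04d}_mat{ch}.png")
            planes.append((np.asarray(img) > 0).astype(np.uint8))
        channels[ch] = np.stack(planes, axis=0)
    return RasterStack(
        channels=channels,
        dot_pitch_mm=tuple(manifest["dot_pitch_mm"]),
        layer_thickness_mm=float(manifest["layer_thickness_mm"]),
        layers=layers,
    )
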