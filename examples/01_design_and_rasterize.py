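"""Design a miniature two-material disc phantom and rasterize it.

Builds a small heterogeneous background, carves out a synthetic "tumor"
ROI, normalizes it to a material mix ratio, composites it into a disc
design, supersamples to a (coarsened, for speed) printer grid and dithers
each layer into the three material bitmap stacks.
"""

import numpy as np

from phantomforge import (
    ImageVolume, Placement, PrinterSpec, SegmentationMask, Units,
    extract_roi, make_disc_design, normalize_unit, write_raster_stack,
)
from phantomforge.print_prep import rasterize_design

rng = np.random.default_rng(0)

# background texture: 8 x 32 x 32 voxels at 1 mm, liver-like 65-125 HU
bg_hu = rng.normal(95, 12, (8, 32, 32)).clip(65, 125)
background = ImageVolume((bg_hu - 65) / 60, (1.0, 1.0, 1.0), units=Units.RATIO)

# a small bright "tumor" in a separate source volume
src = ImageVolume(rng.normal(80, 30, (8, 16, 16)), (1.0, 1.0, 1.0))
mask = np.zeros(src.shape, np.uint8)
mask[2:6, 4:12, 4:12] = 1
tumor = normalize_unit(extract_roi(src, SegmentationMask(mask, src.spacing_mm), "tumor"))

design = make_disc_design(
    background, [tumor], [Placement("tumor", (2, 10, 10))],
    diameter_mm=30.0, thickness_mm=6.0,
)

# a demonstration printer grid: real droplet pitch is 0.048 x 0.084 x 0.030
# mm, which would mean ~10^9 dots even for this miniature part
spec = PrinterSpec(dot_pitch_mm=(0.5, 0.5), layer_thickness_mm=0.5)
stack = rasterize_design(design.background, design.support, spec)
manifest = write_raster_stack(stack, "scratch/raster_demo")

in_part = design.support.data.astype(bool).sum()
print(f"disc design: {design.disc_diameter_mm:.0f} mm x {design.disc_thickness_mm:.0f} mm, "
      f"{in_part} in-part design voxels")
print(f"raster stack: {stack.n_layers} layers of {stack.channels['A'].shape[1:]} dots")
print(f"files written: {manifest['n_files']} (one per layer and material)")
a, b = stack.channels["A"], stack.channels["B"]
sup = np.stack([stack.channels['A'] | stack.channels['B']]).sum()
print(f"material A dots: {a.sum()}, material B dots: {b.sum()}, "
      f"complementary everywhere in-part: {bool(((a + b) <= 1).all())}")
print("Each '1' in a material-A bitmap deposits the high-attenuation resin;")
print("B is its inversion inside the part; channel C stays empty.")
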