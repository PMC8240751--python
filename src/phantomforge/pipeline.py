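"""End-to-end convenience wiring: phantom -> repeat scans -> feature table."""

from __future__ import annotations

import numpy as np

from phantomforge.qc_stats import RepeatabilityResult, ReplicateTable, wcv
from phantomforge.radiomics import (
    FEATURE_NAMES,
    FeatureConfig,
    extract_feature_vector,
)
from phantomforge.scansim import DigitalPhantom
from phantomforge.volume_io import ImageVolume, SegmentationMask


def extract_replicate_table(phantom: DigitalPhantom,
                            scans: list[ImageVolume],
                            config: FeatureConfig | None = None,
                            names: tuple[str, ...] = FEATURE_NAMES) -> ReplicateTable:
    """Extract the feature panel for every lesion in every replicate scan.

    Each lesion is cropped to its bounding box before extraction; features
    are computed over the lesion's own mask.
    """
    config = config or FeatureConfig()
    crops = []
    for m in phantom.lesion_masks:
        fg = m.data > 0
        co = np.argwhere(fg)
        lo, hi = co.min(axis=0), co.max(axis=0) + 1
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        crops.append((box, fg[box]))
    values = np.zeros((len(crops), len(scans), len(names)))
    for j, scan in enumerate(scans):
        for i, (box, mask) in enumerate(crops):
            fv = extract_feature_vector(
                ImageVolume(scan.data[box], scan.spacing_mm),
                SegmentationMask(mask, scan.spacing_mm),
                config, roi_label=f"lesion_{i}", names=names)
            values[i, j] = [fv[k] for k in names]
    return ReplicateTable(values,
                          [f"lesion_{i}" for i in range(len(crops))],
                          list(names))


def repeatability_by_feature(table: ReplicateTable) -> dict[str, list[RepeatabilityResult]]:
    """wCV results (per lesion + pooled) for every feature in the table."""
    return {feat: wcv(table, feat) for feat in table.feature_names}


def max_lesion_wcv(table: ReplicateTable) -> float:
    """The worst per-lesion wCV over all features — the repeatability headline."""
    worst = 0.0
    for results in repeatability_by_feature(table).values():
        for res in results:
            if res.roi != "pooled":
                worst = max(worst, res.wcv_pct)
    return worst
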