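"""Repeatability and reproducibility statistics for replicate feature tables.

Repeatability of a feature over repeat scans is summarized by the
within-subject coefficient of variation, wCV% = sigma_w / mu * 100, with a
chi-squared pivotal 95% confidence interval; wCV below 10% counts as
repeatable. Reproducibility across scan modes is the percent deviation
pDV% = (mean_new - mean_ref) / mean_ref * 100, tested against the reference
with a one-sample Wilcoxon signed-rank test and summarized by the effect
size r = Z / sqrt(N_obs) with a bootstrap confidence interval. Image-level
agreement uses the structural similarity index (SSIM).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REPEATABLE_WCV_PCT = 10.0
SIGNIFICANCE_LEVEL = 0.05
EXACT_WILCOXON_MAX_N = 12


@dataclass
class ReplicateTable:
    """Feature values indexed (roi, replicate, feature), no missing entries."""

    values: np.ndarray
    roi_labels: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (roi, replicate, feature)")
        n_roi, n_rep, n_feat = self.values.shape
        if n_rep < 2:
            raise ValueError("need at least 2 replicates per ROI")
        if len(self.roi_labels) != n_roi or len(self.feature_names) != n_feat:
            raise ValueError("label lists must match the value array shape")
        if not np.isfinite(self.values).all():
            raise ValueError("replicate table contains missing/non-finite values")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReplicateTable":
        """Build from a tidy frame with columns roi, replicate, feature, value."""
        pivot = frame.pivot_table(index=["roi", "replicate"], columns="feature",
                                  values="value")
        if pivot.isna().any().any():
            raise ValueError("replicate table has missing cells")
        rois = list(pivot.index.get_level_values("roi").unique())
        feats = list(pivot.columns)
        n_rep = len(pivot.loc[rois[0]])
        values = np.stack([pivot.loc[r].to_numpy()[:n_rep] for r in rois])
        return cls(values, [str(r) for r in rois], [str(f) for f in feats])


@dataclass(frozen=True)
class RepeatabilityResult:
    feature: str
    roi: str                       # ROI label, or "pooled"
    wcv_pct: float
    ci95: tuple[float, float]
    n_subjects: int
    dof: int

    @property
    def repeatable(self) -> bool:
        return self.wcv_pct < REPEATABLE_WCV_PCT


@dataclass(frozen=True)
class DeviationResult:
    feature: str
    roi: str
    scan_mode: str
    mean_new: float
    mean_ref: float
    pdv_pct: float
    p_value: float
    z_score: float
    effect_size_r: float
    r_ci95: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


# ---------------------------------------------------------------------------
# Repeatability


def wcv_ci(wcv_pct: float, n_subjects: int, n_replicates: int) -> tuple[float, float]:
    """Chi-squared pivotal 95% CI for the within-subject CV.

    dof = N * (replicates - 1); bound = wCV * sqrt(dof / chi2_{dof, alpha})
    with lower-tail quantile probabilities alpha = 0.975 (lower bound) and
    0.025 (upper bound).
    """
    dof = n_subjects * (n_replicates - 1)
    if dof < 1:
        raise ValueError(f"dof = {dof} < 1; need more replicates")
    lo = wcv_pct * float(np.sqrt(dof / stats.chi2.ppf(0.975, dof)))
    hi = wcv_pct * float(np.sqrt(dof / stats.chi2.ppf(0.025, dof)))
    return (lo, hi)


def wcv(table: ReplicateTable, feature: str) -> list[RepeatabilityResult]:
    """Within-subject CV per ROI plus a pooled estimate across ROIs.

    Per ROI: sigma_w is the sample SD over replicates and mu their mean.
    Pooled: sigma_w^2 is the mean of the per-ROI replicate variances
    (balanced design) and mu the grand mean. Results whose mean is zero are
    undefined and rejected.
    """
    j = table.feature_names.index(feature)
    vals = table.values[:, :, j]
    n_roi, n_rep = vals.shape
    results = []
    # pivot-shift before the variance: mathematically a no-op, but it keeps
    # bit-identical replicates at variance exactly 0
    per_roi_var = (vals - vals[:, :1]).var(axis=1, ddof=1)
    for i, roi in enumerate(table.roi_labels):
        mu = vals[i].mean()
        if mu == 0:
            raise ValueError(f"mean of feature '{feature}' for ROI '{roi}' is zero; "
                             "wCV undefined")
        w = float(np.sqrt(per_roi_var[i]) / abs(mu) * 100.0)
        results.append(RepeatabilityResult(
            feature=feature, roi=roi, wcv_pct=w,
            ci95=wcv_ci(w, 1, n_rep), n_subjects=1, dof=n_rep - 1,
        ))
    grand_mu = vals.mean()
    if grand_mu == 0:
        raise ValueError(f"grand mean of feature '{feature}' is zero; wCV undefined")
    pooled = float(np.sqrt(per_roi_var.mean()) / abs(grand_mu) * 100.0)
    results.append(RepeatabilityResult(
        feature=feature, roi="pooled", wcv_pct=pooled,
        ci95=wcv_ci(pooled, n_roi, n_rep),
        n_subjects=n_roi, dof=n_roi * (n_rep - 1),
    ))
    return results


# ---------------------------------------------------------------------------
# Reproducibility


def pdv(mean_new: float, mean_ref: float) -> float:
    """Percent deviation of a scan-mode mean from the reference mean."""
    if mean_ref == 0:
        raise ValueError("reference mean is zero; pDV undefined")
    return (mean_new - mean_ref) / mean_ref * 100.0


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(diffs))  # mid-ranks on ties
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks


def wilcoxon_one_sample(values: np.ndarray | list, reference: float) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against ``reference``.

    Returns (p_value, Z). Exact-zero differences are dropped. For n <= 12
    remaining differences the null distribution of W+ is enumerated exactly
    over all 2^n sign patterns of the observed rank magnitudes; larger n
    uses the normal approximation with tie correction and a 0.5 continuity
    correction. Z is always the normal-approximation z-score, reported
    alongside the exact p when the exact path runs.
    """
    diffs = np.asarray(values, dtype=np.float64) - reference
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1.0", stacklevel=2)
        return 1.0, 0.0
    w_plus, ranks = _signed_rank_statistic(diffs)

    # normal approximation Z with tie correction and continuity correction
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var_w <= 0:
        z = 0.0
    else:
        delta = w_plus - mean_w
        z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var_w) if delta != 0 else 0.0

    if n <= EXACT_WILCOXON_MAX_N:
        totals = np.array([
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((False, True), repeat=n)
        ])
        n_pat = totals.size
        p_le = np.count_nonzero(totals <= w_plus + 1e-9) / n_pat
        p_ge = np.count_nonzero(totals >= w_plus - 1e-9) / n_pat
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        if var_w <= 0:
            p = 1.0
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
    return float(p), float(z)


def effect_size_r(z: float, n_obs: int) -> float:
    """Effect size r = Z / sqrt(N_obs), in [-1, 1]."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    r = z / np.sqrt(n_obs)
    if abs(r) > 1:
        warnings.warn(f"|r| = {abs(r):.3f} > 1; clipping to the unit interval",
                      stacklevel=2)
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)


def bootstrap_ci(sample: np.ndarray | list, statistic, n_boot: int = 100,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile 95% bootstrap CI of ``statistic`` over ``sample``."""
    sample = np.asarray(sample, dtype=np.float64)
    if sample.size < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = statistic(rng.choice(sample, size=sample.size, replace=True))
    return (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))


def scan_mode_deviation(new_values: np.ndarray | list, ref_values: np.ndarray | list,
                        feature: str = "", roi: str = "", scan_mode: str = "",
                        n_boot: int = 100, seed: int = 0) -> DeviationResult:
    """Full pDV workflow for one (feature, ROI, scan mode) cell.

    ``ref_values`` are the reference-protocol replicates (their mean is the
    baseline), ``new_values`` the replicates under the perturbed mode.
    """
    new_values = np.asarray(new_values, dtype=np.float64)
    ref_values = np.asarray(ref_values, dtype=np.float64)
    mean_ref = float(ref_values.mean())
    mean_new = float(new_values.mean())
    d = pdv(mean_new, mean_ref)
    p, z = wilcoxon_one_sample(new_values, mean_ref)
    n_obs = new_values.size
    r = effect_size_r(z, n_obs)

    def r_stat(resample: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, z_b = wilcoxon_one_sample(resample, mean_ref)
            return effect_size_r(z_b, resample.size)

    r_ci = bootstrap_ci(new_values, r_stat, n_boot=n_boot, seed=seed)
    return DeviationResult(
        feature=feature, roi=roi, scan_mode=scan_mode,
        mean_new=mean_new, mean_ref=mean_ref, pdv_pct=d,
        p_value=p, z_score=z, effect_size_r=r, r_ci95=r_ci,
    )


# ---------------------------------------------------------------------------
# Image similarity


def ssim(image_a: np.ndarray, image_b: np.ndarray, dynamic_range: float) -> float:
    """Mean structural similarity index with the canonical parameters.

    Gaussian window (sigma = 1.5, 11 x 11 taps), K1 = 0.01, K2 = 0.03 over
    the stated dynamic range. Works on 2D or 3D arrays of equal shape.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    from skimage.metrics import structural_similarity

    return float(structural_similarity(
        a, b, data_range=dynamic_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03,
    ))


# ---------------------------------------------------------------------------
# Report generation


def qc_report(reference: ReplicateTable,
              modes: dict[str, ReplicateTable] | None = None,
              n_boot: int = 100, seed: int = 0) -> pd.DataFrame:
    """Tidy QC report: wCV (+CI, repeatable flag) and per-mode pDV stats."""
    rows = []
    for feature in reference.feature_names:
        for res in wcv(reference, feature):
            rows.append({
                "kind": "repeatability", "feature": res.feature, "roi": res.roi,
                "scan_mode": "reference", "wcv_pct": res.wcv_pct,
                "wcv_ci_lo": res.ci95[0], "wcv_ci_hi": res.ci95[1],
                "repeatable": res.repeatable,
            })
    for mode_name, table in (modes or {}).items():
        for feature in reference.feature_names:
            j_ref = reference.feature_names.index(feature)
            j_new = table.feature_names.index(feature)
            for i, roi in enumerate(table.roi_labels):
                i_ref = reference.roi_labels.index(roi)
                res = scan_mode_deviation(
                    table.values[i, :, j_new], reference.values[i_ref, :, j_ref],
                    feature=feature, roi=roi, scan_mode=mode_name,
                    n_boot=n_boot, seed=seed,
                )
                rows.append({
                    "kind": "deviation", "feature": feature, "roi": roi,
                    "scan_mode": mode_name, "pdv_pct": res.pdv_pct,
                    "p_value": res.p_value, "z_score": res.z_score,
                    "effect_size_r": res.effect_size_r,
                    "r_ci_lo": res.r_ci95[0], "r_ci_hi": res.r_ci95[1],
                    "significant": res.significant,
                })
    return pd.DataFrame(rows)
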