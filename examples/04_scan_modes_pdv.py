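"""Reproducibility across scan modes: percent deviation from baseline.

Simulates the reference protocol and a few perturbed scan modes, extracts
features under each, and reports the percent deviation (pDV) of each
feature's mean from the baseline mean together with the Wilcoxon p-value
and effect size r.
"""

from phantomforge import (
    SCAN_MODE_PRESETS, apply_scan_mode, generate_digital_phantom,
    simulate_repeat_scans,
)
from phantomforge.pipeline import extract_replicate_table
from phantomforge.qc_stats import scan_mode_deviation

phantom = generate_digital_phantom(seed=11, n_lesions=1,
                                   extent_vox=(24, 72, 72), min_lesion_vox=12**3)
baseline_scans = simulate_repeat_scans(phantom, n=10, noise_sigma_hu=5.0, seed=1)
baseline = extract_replicate_table(phantom, baseline_scans)

print(f"{'mode':12s} {'feature':22s} {'pDV %':>9s} {'p':>8s} {'r':>7s}")
for mode_name in ("asir30", "bone", "ma100"):
    mode = SCAN_MODE_PRESETS[mode_name]
    scans = [apply_scan_mode(s, mode, seed=100 + i)
             for i, s in enumerate(simulate_repeat_scans(
                 phantom, n=10, noise_sigma_hu=0.0, seed=1))]
    table = extract_replicate_table(phantom, scans)
    for j, feature in enumerate(table.feature_names):
        res = scan_mode_deviation(
            table.values[0, :, j], baseline.values[0, :, j],
            feature=feature, roi="lesion_0", scan_mode=mode_name, seed=5)
        flag = "*" if res.significant else ""
        print(f"{mode_name:12s} {feature:22s} {res.pdv_pct:9.2f} "
              f"{res.p_value:8.4f} {res.effect_size_r:7.3f}{flag}")
print("\npDV > 0: the mode inflates the feature (sharpening, added noise);")
print("pDV < 0: it suppresses it (smoothing). '*' marks p < 0.05 on the")
print("one-sample Wilcoxon test against the baseline mean.")
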