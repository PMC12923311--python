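"""Whole-kidney TIC features and per-pixel parametric maps.

Computes time-to-peak (TTP), peak intensity (PI) and the area-under-
curve decomposition (AUC = AUrC + AUfC) for one simulated animal, as a
whole-organ curve and pixel-wise.  AUrC is inflow (start to peak), AUfC
is washout plus retention (peak to end); their sum equals AUC exactly.
"""

import numpy as np

from nbceus.synthetic import generate_cohort
from nbceus.tic import map_histogram, parametric_maps, tic_features, whole_organ_tic

series, truth = generate_cohort(1, 1, seed=7)[1]  # the injury animal

tic = whole_organ_tic(series)
f = tic_features(tic, smooth_window=5)
print(f"whole-kidney TIC ({len(tic)} samples over {tic.times_s[-1]:.0f} s):")
print(f"  TTP  = {f.ttp_s:8.1f} s   (delayed by impaired perfusion)")
print(f"  PI   = {f.pi:8.1f} a.u.")
print(f"  AUC  = {f.auc:8.0f} a.u.*s = AUrC {f.aurc:.0f} + AUfC {f.aufc:.0f}")
print(f"  decomposition error: {abs(f.aurc + f.aufc - f.auc):.2e}")

maps = parametric_maps(series, smooth_window=5)
summ = map_histogram(maps.aufc, series.mask)
print(f"\nper-pixel AUfC map over {summ.n} kidney pixels:")
print(f"  median {summ.percentiles[50]:.0f}, p95 {summ.percentiles[95]:.0f} a.u.*s")
frac_hot = np.mean(maps.aufc[series.mask] > 2 * summ.percentiles[50])
print(f"  fraction above 2x median: {frac_hot:.2f}")
print("the high-AUfC tail marks the retention patches where extravasated")
print("contrast accumulates; compare with truth.retention_fraction =",
      f"{truth.retention_fraction:.2f}")
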