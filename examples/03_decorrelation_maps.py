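"""Pixel-wise decorrelation-time (DT) mapping across acquisitions.

DT is the lag at which a pixel's z-scored signal autocorrelation falls
to 0.5: fast-moving intravascular contrast decorrelates within a frame
or two, stationary extravasated contrast over tens of seconds.  The
example prints the per-acquisition DT summary for one control and one
injury animal — the injury metrics should diverge in the late phase
(acquisitions 4-6) and overlap early.
"""

from nbceus.decorrelation import DTConfig, dt_map, dt_summary
from nbceus.synthetic import generate_cohort

cohort = generate_cohort(1, 1, seed=11)
config = DTConfig()  # threshold 0.5, 10-s retention count, cap at half window

for series, truth in cohort:
    print(f"\n{truth.animal_id} ({truth.group_label}), retention fraction "
          f"{truth.retention_fraction:.2f}")
    print(f"  {'aq':>3s} {'mean DT (s)':>12s} {'variance':>10s} {'px > 10 s':>10s}")
    for loop in series.loops:
        s = dt_summary(dt_map(loop, series.mask, config), config)
        print(f"  {loop.acquisition_index:3d} {s.mean_dt_s:12.2f} "
              f"{s.dt_variance_s2:10.2f} {s.n_pixels_above_threshold:10d}")

print("\nmean DT tracks overall contrast retention, DT variance its patchiness,")
print("and the >10-s count the extravasated area; all three stay near the")
print("noise floor for the control animal at every acquisition.")
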