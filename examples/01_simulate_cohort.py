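"""Simulate a two-group contrast-ultrasound cohort and inspect its truth.

Generates 2 control ("sham") and 2 injury ("iri") kidneys at desk scale
and prints, per animal, the ground-truth severity (retention-pixel
fraction) and mean wash-in peak time.  Injury animals should show a
clearly larger retention fraction and a somewhat delayed peak.
"""

import numpy as np

from nbceus.synthetic import generate_cohort

cohort = generate_cohort(n_sham=2, n_iri=2, seed=42)

print(f"{'animal':10s} {'group':5s} {'retention':>9s} {'mean t_p (s)':>12s} {'mask px':>8s}")
for series, truth in cohort:
    mask = truth.class_map.mask
    print(
        f"{truth.animal_id:10s} {truth.group_label:5s} "
        f"{truth.retention_fraction:9.3f} "
        f"{truth.peak_time_s[mask].mean():12.1f} {int(mask.sum()):8d}"
    )

loop = cohort[0][0].loops[0]
print(
    f"\neach animal: {len(cohort[0][0].loops)} acquisitions x "
    f"{loop.n_frames} frames at {loop.frame_interval_s} s "
    f"({loop.n_frames * loop.frame_interval_s:.0f}-s windows)"
)
print("retention fraction ~0.02 for sham vs ~0.25 for injury animals;")
print("that fraction is the latent severity all downstream metrics track.")
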