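"""Group comparison and imaging-histology correlation on a full cohort.

Simulates the default 4-control + 6-injury cohort, averages the DT
metrics over the early (Aq 1-3) and late (Aq 4-6) phases, compares the
groups with Welch's t-test and Glass's delta (injury vs control, in
control-SD units), and correlates late-phase imaging with synthetic
histology on the log10 scale.
"""

from nbceus.pipeline import DT_METRICS, cohort_dt_table
from nbceus.stats import compare_groups, correlation_matrix, phase_average
from nbceus.synthetic import generate_cohort, generate_histology

cohort = generate_cohort(4, 6, seed=2024)
dt = cohort_dt_table(cohort)
phases = phase_average(dt[dt["metric"].isin(DT_METRICS)])

comp = compare_groups(phases)
print("group comparisons (Welch p, Glass's delta = (iri-sham)/SD_sham):")
for _, row in comp.iterrows():
    print(f"  {row['acquisition']:5s} {row['metric']:18s} "
          f"sham {row['sham_mean']:8.2f}  iri {row['iri_mean']:8.2f}  "
          f"p={row['p_value']:.4f}  delta={row['glass_delta']:6.1f}")

histology = generate_histology([t for _, t in cohort], seed=1)
late = phases[phases["acquisition"] == "late"]
corr = correlation_matrix(late, histology, transform="log10")
print("\nlate-phase imaging x histology Pearson r (log10 scale):")
for _, row in corr.iterrows():
    print(f"  {row['imaging_metric']:18s} x {row['histology_metric']:28s} "
          f"r={row['r']:5.2f} (n={row['n']})")

print("\nexpected pattern: late-phase p < 0.05 with delta >> 0.8, early-phase")
print("p > 0.05; correlations near the generator's latent coupling of 0.8.")
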