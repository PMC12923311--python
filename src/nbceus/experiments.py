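"""Seeded validation studies over replicated synthetic cohorts.

These drive the package's self-checks: replicate the default two-group
cohort many times and summarize how often the late-phase decorrelation
metrics separate the groups (and the early-phase ones do not), and how
well the imaging–histology correlation target is recovered.  They are
ordinary library functions, usable for power exploration as well.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decorrelation import DTConfig
from .pipeline import DT_METRICS, cohort_dt_table
from .stats import PhaseConfig, compare_groups, correlation_matrix, phase_average
from .synthetic import (
    HistologyParams,
    RenderParams,
    TruthParams,
    generate_cohort,
    generate_histology,
)

__all__ = [
    "replicate_seeds",
    "dt_group_separation_study",
    "separation_rates",
    "correlation_recovery_study",
]


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Deterministic per-replicate seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_replicates)]


def _phase_dt_tables(seed: int, n_sham: int, n_iri: int, truth_params, render_params, dt_config, phases):
    cohort = generate_cohort(
        n_sham, n_iri, truth_params, seed=seed, render_params=render_params
    )
    dt_table = cohort_dt_table(cohort, dt_config)
    core = dt_table[dt_table["metric"].isin(DT_METRICS)]
    return cohort, phase_average(core, phases)


def dt_group_separation_study(
    n_replicates: int = 100,
    seed: int = 0,
    n_sham: int = 4,
    n_iri: int = 6,
    truth_params: TruthParams | None = None,
    render_params: RenderParams | None = None,
    dt_config: DTConfig | None = None,
    phases: PhaseConfig | None = None,
) -> pd.DataFrame:
    """Welch p and Glass's Δ per replicate, phase and DT metric.

    Each replicate simulates an independent default cohort (4 sham-like
    + 6 injury-like animals at desk scale), computes per-animal
    early/late phase averages of mean DT, DT variance and the
    pixels-above-threshold count, and compares the groups.  Returns a
    long DataFrame with columns ``replicate, acquisition (phase),
    metric, p_value, glass_delta, ...``.
    """
    phases = phases or PhaseConfig()
    rows = []
    for rep, rep_seed in enumerate(replicate_seeds(seed, n_replicates)):
        _, phase_table = _phase_dt_tables(
            rep_seed, n_sham, n_iri, truth_params, render_params, dt_config, phases
        )
        comp = compare_groups(phase_table)
        comp["replicate"] = rep
        rows.append(comp)
    return pd.concat(rows, ignore_index=True)


def separation_rates(study: pd.DataFrame, alpha: float = 0.05, min_delta: float = 0.8) -> pd.DataFrame:
    """Fraction of replicates meeting the separation criterion per
    phase and metric: late phase should be significant with a large
    positive effect, early phase non-significant."""
    out = []
    for (phase, metric), sub in study.groupby(["acquisition", "metric"], sort=True):
        n = len(sub)
        out.append(
            {
                "phase": phase,
                "metric": metric,
                "n_replicates": n,
                "frac_significant_large": float(
                    ((sub["p_value"] < alpha) & (sub["glass_delta"] >= min_delta)).mean()
                ),
                "frac_nonsignificant": float((sub["p_value"] >= alpha).mean()),
                "median_p": float(sub["p_value"].median()),
                "median_delta": float(sub["glass_delta"].median()),
            }
        )
    return pd.DataFrame(out)


def correlation_recovery_study(
    n_cohorts: int = 50,
    seed: int = 0,
    n_sham: int = 4,
    n_iri: int = 6,
    target_correlation: float = 0.8,
    truth_params: TruthParams | None = None,
    render_params: RenderParams | None = None,
    dt_config: DTConfig | None = None,
    phases: PhaseConfig | None = None,
) -> pd.DataFrame:
    """Recovered late-phase DT-metric × histology Pearson r per cohort.

    Histology read-outs are generated at the configured latent
    correlation to each animal's true severity; correlations are then
    computed exactly as the analysis pipeline would (log10 transform,
    per-animal late-phase averages).  Returns one row per cohort ×
    imaging metric × histology metric.
    """
    phases = phases or PhaseConfig()
    hp = HistologyParams(target_correlation=target_correlation)
    rows = []
    for rep, rep_seed in enumerate(replicate_seeds(seed, n_cohorts)):
        cohort, phase_table = _phase_dt_tables(
            rep_seed, n_sham, n_iri, truth_params, render_params, dt_config, phases
        )
        histology = generate_histology(
            [t for _, t in cohort], hp, seed=(rep_seed + 1) & 0x7FFFFFFF
        )
        late = phase_table[phase_table["acquisition"] == "late"]
        corr = correlation_matrix(late, histology, transform="log10")
        corr["cohort"] = rep
        rows.append(corr)
    return pd.concat(rows, ignore_index=True)
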