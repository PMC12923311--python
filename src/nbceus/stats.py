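"""Group comparisons and imaging–histology correlation analysis.

Two-group comparisons use Welch's unequal-variance t-test together with
Glass's Δ — the difference of group means in units of the *control*
(sham) group's sample standard deviation — which conveys effect
magnitude in small-animal cohorts where p-values alone are uninformative.
Correlations are product–moment Pearson r, by convention computed on
log10-transformed values for density-like quantities spanning decades
(a Spearman alternative is available).

Metric tables are long-format pandas DataFrames with columns
``animal_id, group, acquisition (optional), metric, value``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "PhaseConfig",
    "welch_t",
    "glass_delta",
    "pearson_corr",
    "phase_average",
    "compare_groups",
    "correlation_matrix",
]

GROUPS = ("sham", "iri")
HISTOLOGY_METRICS = (
    "tubular_injury_score",
    "neutrophil_density",
    "extravascular_signal_density",
)


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    sham_mean: float
    iri_mean: float
    t_statistic: float
    welch_df: float
    p_value: float
    glass_delta: float
    acquisition: object = None  # acquisition index or phase label


@dataclass(frozen=True)
class CorrelationResult:
    x_metric: str
    y_metric: str
    r: float
    n: int
    p_value: float
    transform: str = "identity"


@dataclass(frozen=True)
class PhaseConfig:
    """Early/late acquisition split (defaults: Aq 1–3 vs Aq 4–6)."""

    early_acquisitions: frozenset = field(default_factory=lambda: frozenset({1, 2, 3}))
    late_acquisitions: frozenset = field(default_factory=lambda: frozenset({4, 5, 6}))

    def __post_init__(self) -> None:
        early = frozenset(self.early_acquisitions)
        late = frozenset(self.late_acquisitions)
        if not early or not late or early & late:
            raise ValueError("phases must be disjoint and non-empty")
        object.__setattr__(self, "early_acquisitions", early)
        object.__setattr__(self, "late_acquisitions", late)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test of b versus a.

    Returns ``(t, df, p)`` with t = (mean_b − mean_a)/sqrt(sa²/na + sb²/nb),
    Welch–Satterthwaite degrees of freedom, and a two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both groups have zero variance with unequal means")
    sa, sb = va / a.size, vb / b.size
    t = (b.mean() - a.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def glass_delta(treated, control) -> float:
    """Glass's Δ: (mean_treated − mean_control) / sample SD of control."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if c.size < 2:
        raise ValueError("control group needs at least 2 observations")
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValueError("control group has zero standard deviation")
    return float((t.mean() - c.mean()) / sd)


def _log10_pairs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = (x > 0) & (y > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("log10 transform dropped %d non-positive pair(s)", dropped)
    return np.log10(x[ok]), np.log10(y[ok])


def pearson_corr(x, y, transform: str = "identity", method: str = "pearson") -> CorrelationResult:
    """Correlation of two paired samples, optionally on the log10 scale.

    Non-positive values are dropped pairwise under the log10 transform.
    Zero variance in either variable yields a missing (NaN) r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if transform == "log10":
        x, y = _log10_pairs(x, y)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 valid pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult("x", "y", float("nan"), n, float("nan"), transform)
    if method == "pearson":
        r, p = sstats.pearsonr(x, y)
    elif method == "spearman":
        r, p = sstats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult("x", "y", float(r), n, float(p), transform)


def phase_average(table: pd.DataFrame, phases: PhaseConfig | None = None) -> pd.DataFrame:
    """Per-animal mean of each metric over the early and late phases.

    Animals missing some acquisitions (e.g., death late in the scan) are
    averaged over the acquisitions they have; an animal with none in a
    phase is absent from that phase's rows.
    """
    phases = phases or PhaseConfig()
    if "acquisition" not in table.columns:
        raise ValueError("table has no 'acquisition' column")
    frames = []
    for label, members in (("early", phases.early_acquisitions), ("late", phases.late_acquisitions)):
        sub = table[table["acquisition"].isin(members)]
        if sub.empty:
            continue
        agg = (
            sub.groupby(["animal_id", "group", "metric"], as_index=False, sort=True)["value"]
            .mean()
        )
        agg["acquisition"] = label
        frames.append(agg)
    if not frames:
        raise ValueError("no acquisitions fall into the configured phases")
    out = pd.concat(frames, ignore_index=True)
    return out[["animal_id", "group", "acquisition", "metric", "value"]]


def compare_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Welch's t and Glass's Δ (injury vs. sham) per metric.

    If the table has an ``acquisition`` column the comparison is made
    separately per acquisition (or phase label).  Output is sorted, so
    it is invariant to the row order of the input.
    """
    df = table.copy()
    has_aq = "acquisition" in df.columns
    if not has_aq:
        df["acquisition"] = "all"
    rows = []
    for (metric, aq), sub in df.groupby(["metric", "acquisition"], sort=True, dropna=False):
        sham = sub.loc[sub["group"] == "sham", "value"].to_numpy()
        iri = sub.loc[sub["group"] == "iri", "value"].to_numpy()
        if sham.size < 2 or iri.size < 2:
            continue
        try:
            t, dfree, p = welch_t(sham, iri)
        except ValueError:  # both groups degenerate with unequal means
            t, dfree, p = float("nan"), float("nan"), float("nan")
        try:
            delta = glass_delta(iri, sham)
        except ValueError:  # zero control SD: report the limit
            diff = float(iri.mean() - sham.mean())
            delta = 0.0 if diff == 0 else float(np.copysign(np.inf, diff))
        rows.append(
            {
                "metric": metric,
                "acquisition": aq,
                "sham_mean": float(sham.mean()),
                "iri_mean": float(iri.mean()),
                "t_statistic": t,
                "welch_df": dfree,
                "p_value": p,
                "glass_delta": delta,
            }
        )
    out = pd.DataFrame(rows)
    if not has_aq and not out.empty:
        out = out.drop(columns=["acquisition"])
    return out


def correlation_matrix(
    imaging: pd.DataFrame,
    histology: pd.DataFrame,
    transform: str = "log10",
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise correlations of imaging metrics against histology.

    ``imaging`` is a long metric table (optionally with a phase label in
    its ``acquisition`` column); ``histology`` is the per-animal table.
    Returns one row per (imaging metric [, phase], histology metric).
    """
    histo_metrics = [c for c in HISTOLOGY_METRICS if c in histology.columns]
    if not histo_metrics:
        raise ValueError("histology table has no recognized metric columns")
    img = imaging.copy()
    if "acquisition" not in img.columns:
        img["acquisition"] = "all"
    rows = []
    for (metric, aq), sub in img.groupby(["metric", "acquisition"], sort=True, dropna=False):
        merged = sub.merge(histology, on="animal_id", how="inner")
        if len(merged) < 3:
            continue
        for hm in histo_metrics:
            try:
                res = pearson_corr(merged["value"], merged[hm], transform=transform, method=method)
            except ValueError:
                # fewer than 3 usable pairs (e.g. all-zero counts under log10)
                res = CorrelationResult("x", "y", float("nan"), 0, float("nan"), transform)
            rows.append(
                {
                    "imaging_metric": metric,
                    "phase": aq,
                    "histology_metric": hm,
                    "r": res.r,
                    "n": res.n,
                    "p_value": res.p_value,
                    "transform": transform,
                }
            )
    return pd.DataFrame(rows)
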