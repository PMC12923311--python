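"""End-to-end orchestration: simulate → parametric → DT → texture → stats.

Also provides the long-format metric-table builders shared by the CLI,
the test suite and the validation studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nbio
from .datatypes import AcquisitionSchedule, AcquisitionSeries
from .decorrelation import DTConfig, dt_map, dt_summary, log_dt_map
from .stats import PhaseConfig, compare_groups, correlation_matrix, phase_average
from .synthetic import (
    RenderParams,
    SyntheticTruth,
    TruthParams,
    generate_cohort,
    generate_histology,
)
from .texture import map_texture
from .tic import map_histogram, parametric_maps, tic_features, whole_organ_tic

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "DT_METRICS",
    "animal_dt_table",
    "cohort_dt_table",
    "cohort_tic_table",
    "cohort_texture_table",
    "run_pipeline",
]

#: names of the per-acquisition DT histogram metrics
DT_METRICS = ("mean_dt_s", "dt_variance_s2", "n_above_threshold")


def animal_dt_table(series: AcquisitionSeries, config: DTConfig | None = None) -> pd.DataFrame:
    """Long-format DT metrics (one row per acquisition × metric)."""
    config = config or DTConfig()
    rows = []
    for loop in series.loops:
        dtm = dt_map(loop, series.mask, config)
        summ = dt_summary(dtm, config)
        for metric, value in (
            ("mean_dt_s", summ.mean_dt_s),
            ("dt_variance_s2", summ.dt_variance_s2),
            ("n_above_threshold", float(summ.n_pixels_above_threshold)),
            ("censored_fraction", summ.censored_fraction),
        ):
            rows.append(
                {
                    "animal_id": series.animal_id,
                    "group": series.group_label,
                    "acquisition": loop.acquisition_index,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def cohort_dt_table(
    cohort: list[AcquisitionSeries] | list[tuple[AcquisitionSeries, SyntheticTruth]],
    config: DTConfig | None = None,
) -> pd.DataFrame:
    """DT metric table for a whole cohort."""
    tables = []
    for item in cohort:
        series = item[0] if isinstance(item, tuple) else item
        tables.append(animal_dt_table(series, config))
    return pd.concat(tables, ignore_index=True)


def cohort_tic_table(
    cohort,
    smooth_window: int = 5,
    baseline_frames: int = 0,
) -> pd.DataFrame:
    """Whole-organ TIC features per animal, long format (no acquisition)."""
    rows = []
    for item in cohort:
        series = item[0] if isinstance(item, tuple) else item
        tic = whole_organ_tic(series)
        if baseline_frames:
            vals = np.clip(tic.values - tic.values[:baseline_frames].mean(), 0.0, None)
            tic = type(tic)(times_s=tic.times_s, values=vals)
        feats = tic_features(tic, smooth_window)
        for name in ("ttp_s", "pi", "auc", "aurc", "aufc"):
            rows.append(
                {
                    "animal_id": series.animal_id,
                    "group": series.group_label,
                    "metric": name,
                    "value": float(getattr(feats, name)),
                }
            )
    return pd.DataFrame(rows)


def cohort_texture_table(
    cohort,
    smooth_window: int = 5,
    glcm_levels: int = 32,
    map_names: tuple[str, ...] = ("ttp_s", "pi", "auc", "aurc", "aufc"),
) -> pd.DataFrame:
    """Haralick features of each animal's parametric maps, long format."""
    rows = []
    for item in cohort:
        series = item[0] if isinstance(item, tuple) else item
        maps = parametric_maps(series, smooth_window)
        for name in map_names:
            tv = map_texture(maps[name], series.mask, levels=glcm_levels)
            for feat in ("contrast", "energy", "correlation", "homogeneity"):
                rows.append(
                    {
                        "animal_id": series.animal_id,
                        "group": series.group_label,
                        "metric": f"{name}_{feat}",
                        "value": float(getattr(tv, feat)),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """One YAML-serializable document configuring an end-to-end run."""

    out_dir: str = "nbceus_out"
    seed: int = 0
    # synthetic cohort
    n_sham: int = 4
    n_iri: int = 6
    height: int = 64
    width: int = 64
    # desk-scale protocol: the paper-style 200-s windows at 1/4 frame rate;
    # set frames_per_acquisition=1000, frame_interval_s=0.2 for the full scan
    n_acquisitions: int = 6
    frames_per_acquisition: int = 250
    frame_interval_s: float = 0.8
    # analysis
    smooth_window: int = 5
    baseline_frames: int = 0
    correlation_threshold: float = 0.5
    max_lag_fraction: float = 0.5
    dt_threshold_s: float = 10.0
    censor_policy: str = "assign_cap"
    glcm_levels: int = 32
    transform: str = "log10"
    early_acquisitions: tuple = (1, 2, 3)
    late_acquisitions: tuple = (4, 5, 6)
    target_correlation: float = 0.8

    @property
    def schedule(self) -> AcquisitionSchedule:
        return AcquisitionSchedule(
            n_acquisitions=self.n_acquisitions,
            frames_per_acquisition=self.frames_per_acquisition,
            frame_interval_s=self.frame_interval_s,
        )

    @property
    def dt_config(self) -> DTConfig:
        return DTConfig(
            correlation_threshold=self.correlation_threshold,
            max_lag_fraction=self.max_lag_fraction,
            dt_threshold_s=self.dt_threshold_s,
            censor_policy=self.censor_policy,
        )

    @property
    def phases(self) -> PhaseConfig:
        return PhaseConfig(
            early_acquisitions=frozenset(self.early_acquisitions),
            late_acquisitions=frozenset(self.late_acquisitions),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["early_acquisitions"] = list(self.early_acquisitions)
        d["late_acquisitions"] = list(self.late_acquisitions)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "early_acquisitions" in d:
            d["early_acquisitions"] = tuple(d["early_acquisitions"])
        if "late_acquisitions" in d:
            d["late_acquisitions"] = tuple(d["late_acquisitions"])
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig, write_cine: bool = False) -> RunManifest:
    """Simulate a cohort and run every analysis stage, writing all outputs.

    ``write_cine=True`` additionally stores the raw cine stacks as
    multi-page TIFFs (large; off by default).  Numeric outputs are
    bit-identical across runs with the same config and seed.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    outputs: dict[str, list[str]] = {}

    def record(stage: str, path: Path) -> Path:
        outputs.setdefault(stage, []).append(str(path.relative_to(out)))
        return path

    try:
        _stage("simulate")
        cohort = generate_cohort(
            config.n_sham,
            config.n_iri,
            TruthParams(),
            seed=config.seed,
            schedule=config.schedule,
            render_params=RenderParams(),
            height=config.height,
            width=config.width,
        )
        nbio.write_schedule(config.schedule, record("simulate", out / "schedule.json"))
        histology = generate_histology(
            [t for _, t in cohort],
            seed=np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] & 0x7FFFFFFF,
        )
        histology.to_csv(record("simulate", out / "histology.csv"), index=False)
        for series, truth in cohort:
            nbio.write_mask(series.mask, record("simulate", out / "masks" / f"{series.animal_id}_mask.tif"))
            if write_cine:
                for p in nbio.write_cine(series, out / "cine"):
                    record("simulate", p)

        _stage("parametric")
        tic_table = cohort_tic_table(cohort, config.smooth_window, config.baseline_frames)
        tic_wide = tic_table.pivot_table(
            index=["animal_id", "group"], columns="metric", values="value", sort=True
        ).reset_index()[["animal_id", "group", "ttp_s", "pi", "auc", "aurc", "aufc"]]
        tic_wide.to_csv(record("parametric", out / "tic_features.csv"), index=False)

        hist_rows = []
        maps_dir = out / "maps"
        for series, _ in cohort:
            maps = parametric_maps(series, config.smooth_window, config.baseline_frames)
            for name, arr in maps.items():
                nbio.write_map(arr, record("parametric", maps_dir / f"{series.animal_id}_{name}.tif"))
                summ = map_histogram(arr, series.mask)
                hist_rows.append(
                    {
                        "animal_id": series.animal_id,
                        "group": series.group_label,
                        "map": name,
                        "mean": summ.mean,
                        "variance": summ.variance,
                        "skewness": summ.skewness,
                        "p5": summ.percentiles[5],
                        "p50": summ.percentiles[50],
                        "p95": summ.percentiles[95],
                    }
                )
        pd.DataFrame(hist_rows).to_csv(record("parametric", out / "map_histograms.csv"), index=False)

        _stage("dtmap")
        dt_cfg = config.dt_config
        dt_table = cohort_dt_table(cohort, dt_cfg)
        dt_dir = out / "dt_maps"
        for series, _ in cohort:
            for loop in series.loops:
                dtm = dt_map(loop, series.mask, dt_cfg)
                nbio.write_map(
                    dtm.dt_s, record("dtmap", dt_dir / f"{series.animal_id}_aq{loop.acquisition_index}_dt.tif")
                )
                nbio.write_map(
                    log_dt_map(dtm, dt_cfg),
                    record("dtmap", dt_dir / f"{series.animal_id}_aq{loop.acquisition_index}_logdt.tif"),
                )
        dt_wide = dt_table.pivot_table(
            index=["animal_id", "group", "acquisition"], columns="metric", values="value", sort=True
        ).reset_index()
        dt_wide.to_csv(record("dtmap", out / "dt_metrics.csv"), index=False)

        _stage("texture")
        texture_table = cohort_texture_table(cohort, config.smooth_window, config.glcm_levels)
        texture_table.pivot_table(
            index=["animal_id", "group"], columns="metric", values="value", sort=True
        ).reset_index().to_csv(record("texture", out / "texture_features.csv"), index=False)

        _stage("stats")
        core_dt = dt_table[dt_table["metric"].isin(DT_METRICS)]
        phases = config.phases
        phase_table = phase_average(core_dt, phases)
        comparisons = pd.concat(
            [
                compare_groups(core_dt).assign(table="dt_per_acquisition"),
                compare_groups(phase_table).assign(table="dt_phase"),
                compare_groups(tic_table).assign(table="tic"),
                compare_groups(texture_table).assign(table="texture"),
            ],
            ignore_index=True,
        )
        comparisons.to_csv(record("stats", out / "group_comparisons.csv"), index=False)
        correlations = correlation_matrix(phase_table, histology, transform=config.transform)
        correlations.to_csv(record("stats", out / "correlations.csv"), index=False)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise RuntimeError(f"pipeline failed during a stage: {exc}") from exc

    manifest.outputs = outputs
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest
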