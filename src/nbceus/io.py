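"""File I/O: multi-page TIFF cine stacks, masks, maps, tables, configs.

Canonical on-disk formats:

* cine loops — one multi-page 32-bit float TIFF per acquisition;
* masks — single-page TIFF, 0 outside / 255 inside;
* parametric and DT maps — single-page 32-bit float TIFF, NaN = missing;
* metric, histology and statistics tables — CSV with stable headers;
* acquisition schedule — JSON sidecar; pipeline configuration — YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import AcquisitionSchedule, AcquisitionSeries, CineLoop

__all__ = [
    "write_cine",
    "read_cine",
    "write_mask",
    "read_mask",
    "write_map",
    "read_map",
    "write_schedule",
    "read_schedule",
]


def write_cine(series: AcquisitionSeries, out_dir: str | Path, prefix: str | None = None) -> list[Path]:
    """One multi-page float32 TIFF per acquisition; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or series.animal_id
    paths = []
    for loop in series.loops:
        path = out_dir / f"{prefix}_aq{loop.acquisition_index}.tif"
        tifffile.imwrite(path, loop.frames.astype(np.float32))
        paths.append(path)
    return paths


def read_cine(
    paths: list[str | Path],
    schedule: AcquisitionSchedule,
    mask: np.ndarray,
    animal_id: str = "animal",
    group_label: str = "sham",
) -> AcquisitionSeries:
    """Load one animal's acquisitions, validated against the schedule."""
    if len(paths) != schedule.n_acquisitions:
        raise ValueError(
            f"schedule expects {schedule.n_acquisitions} acquisitions, "
            f"got {len(paths)} file(s)"
        )
    loops = []
    shape = None
    for i, path in enumerate(paths, start=1):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"cine file for acquisition {i} missing: {path}")
        frames = np.asarray(tifffile.imread(path), dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.shape[0] != schedule.frames_per_acquisition:
            raise ValueError(
                f"{path.name}: {frames.shape[0]} pages, schedule expects "
                f"{schedule.frames_per_acquisition} (acquisition {i})"
            )
        if shape is None:
            shape = frames.shape[1:]
        elif frames.shape[1:] != shape:
            raise ValueError(f"{path.name}: frame shape {frames.shape[1:]} != {shape}")
        frames = np.clip(frames, 0.0, None)
        loops.append(
            CineLoop(
                frames=frames,
                frame_interval_s=schedule.frame_interval_s,
                acquisition_index=i,
                start_time_s=schedule.start_times_s[i - 1],
            )
        )
    return AcquisitionSeries(loops=loops, mask=mask, animal_id=animal_id, group_label=group_label)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path, expect_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Single-page image to boolean mask (nonzero = inside)."""
    path = Path(path)
    img = np.asarray(tifffile.imread(path))
    if img.ndim != 2:
        raise ValueError(f"{path.name}: mask must be a single-page 2-D image, got shape {img.shape}")
    if expect_shape is not None and img.shape != tuple(expect_shape):
        raise ValueError(f"{path.name}: mask shape {img.shape} does not match cine {expect_shape}")
    return img != 0


def write_map(map_2d: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(map_2d, dtype=np.float32))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_schedule(schedule: AcquisitionSchedule, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(schedule.to_dict(), indent=2) + "\n")
    return path


def read_schedule(path: str | Path) -> AcquisitionSchedule:
    return AcquisitionSchedule.from_dict(json.loads(Path(path).read_text()))
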