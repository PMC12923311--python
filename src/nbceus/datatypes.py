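"""Core containers for dynamic contrast-enhanced ultrasound (CEUS) data.

Conventions used throughout the package:

* images are ``(row, col)`` arrays, 0-based, row 0 at the top;
* time is measured in seconds from contrast injection, frame index 0-based;
* intensities are linear (not log-compressed) and non-negative;
* missing values in float maps are IEEE NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionSchedule",
    "CineLoop",
    "AcquisitionSeries",
    "TIC",
]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Timing layout of a multi-acquisition contrast scan.

    The default mirrors a common small-animal protocol: six contiguous
    acquisitions of 1000 frames at 5 frames per second (3.33-minute
    windows, ~20 minutes total).

    Parameters
    ----------
    n_acquisitions
        Number of continuous imaging windows (Aq 1..n).
    frames_per_acquisition
        Frames captured in each window.
    frame_interval_s
        Seconds between consecutive frames (0.2 s = 5 fps).
    start_times_s
        Start offset of each acquisition from injection.  ``None`` means
        contiguous acquisitions: 0, T, 2T, ... where
        ``T = frames_per_acquisition * frame_interval_s``.
    """

    n_acquisitions: int = 6
    frames_per_acquisition: int = 1000
    frame_interval_s: float = 0.2
    start_times_s: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_acquisitions < 1:
            raise ValueError("n_acquisitions must be >= 1")
        if self.frames_per_acquisition < 2:
            raise ValueError("frames_per_acquisition must be >= 2")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.start_times_s is None:
            window = self.frames_per_acquisition * self.frame_interval_s
            starts = tuple(i * window for i in range(self.n_acquisitions))
            object.__setattr__(self, "start_times_s", starts)
        else:
            starts = tuple(float(t) for t in self.start_times_s)
            if len(starts) != self.n_acquisitions:
                raise ValueError(
                    f"start_times_s has {len(starts)} entries for "
                    f"{self.n_acquisitions} acquisitions"
                )
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise ValueError("start_times_s must be strictly increasing")
            object.__setattr__(self, "start_times_s", starts)

    @property
    def acquisition_duration_s(self) -> float:
        return self.frames_per_acquisition * self.frame_interval_s

    def frame_times_s(self, acquisition_index: int) -> np.ndarray:
        """Absolute sample times (s from injection) of one acquisition.

        ``acquisition_index`` is 1-based, matching the Aq 1..n labelling.
        """
        if not 1 <= acquisition_index <= self.n_acquisitions:
            raise ValueError(f"acquisition_index {acquisition_index} out of range")
        start = self.start_times_s[acquisition_index - 1]
        return start + np.arange(self.frames_per_acquisition) * self.frame_interval_s

    def to_dict(self) -> dict:
        return {
            "n_acquisitions": self.n_acquisitions,
            "frames_per_acquisition": self.frames_per_acquisition,
            "frame_interval_s": self.frame_interval_s,
            "start_times_s": list(self.start_times_s),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSchedule":
        return cls(
            n_acquisitions=int(d["n_acquisitions"]),
            frames_per_acquisition=int(d["frames_per_acquisition"]),
            frame_interval_s=float(d["frame_interval_s"]),
            start_times_s=tuple(d["start_times_s"]) if d.get("start_times_s") else None,
        )


@dataclass
class CineLoop:
    """One continuous acquisition: a time-ordered stack of 2-D frames."""

    frames: np.ndarray  # (T, H, W), non-negative linear intensities
    frame_interval_s: float
    acquisition_index: int = 1  # 1-based Aq label
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("a cine loop needs at least 2 frames")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class AcquisitionSeries:
    """All acquisitions of one animal plus its organ mask."""

    loops: list[CineLoop]
    mask: np.ndarray  # (H, W) boolean organ mask
    animal_id: str = "animal"
    group_label: str = "sham"

    def __post_init__(self) -> None:
        if not self.loops:
            raise ValueError("series needs at least one cine loop")
        self.mask = np.asarray(self.mask).astype(bool)
        shape = self.loops[0].frame_shape
        for loop in self.loops:
            if loop.frame_shape != shape:
                raise ValueError("all loops must share the frame shape")
        if self.mask.shape != shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match frames {shape}"
            )
        starts = [lp.start_time_s for lp in self.loops]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("loops must be ordered by start_time_s")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.loops[0].frame_shape

    @property
    def n_acquisitions(self) -> int:
        return len(self.loops)


@dataclass
class TIC:
    """A time-intensity curve: contrast signal versus time."""

    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times_s and values must be equal-length 1-D arrays")
        if self.times_s.size < 2:
            raise ValueError("a TIC needs at least 2 samples")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size
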