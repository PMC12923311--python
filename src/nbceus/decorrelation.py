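"""Per-pixel echo decorrelation-time (DT) mapping.

A pixel's time–intensity curve within one acquisition window is
z-scored and its sample autocorrelation function (ACF) computed; the
decorrelation time is the lag (in seconds) at which the ACF first drops
to a threshold (default 0.5), with linear interpolation between the
adjacent lags for sub-frame resolution.  Fast-moving intravascular
contrast decorrelates within a frame or two; stationary extravasated
agent keeps the ACF high for many seconds.

For an AR(1) fluctuation with coefficient rho the theoretical ACF is
rho^k, so the expected DT is ``ln(0.5)/ln(rho) * frame_interval`` — the
analytic oracle used in the tests.

Pixels whose ACF never reaches the threshold within the searched lag
range are *censored*: depending on policy they are assigned the cap
(``max_lag * frame_interval``, making mean DT a conservative lower
bound) or excluded.  Zero-variance pixels carry no signal and are
missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CineLoop

__all__ = [
    "DTConfig",
    "DTMap",
    "DTSummary",
    "zscore_series",
    "sample_acf",
    "decorrelation_time",
    "dt_map",
    "dt_summary",
    "log_dt_map",
    "theoretical_ar1_dt",
]


@dataclass(frozen=True)
class DTConfig:
    """Decorrelation-time estimation settings.

    correlation_threshold
        ACF level defining the decorrelation lag (default 0.5).
    max_lag_fraction
        Fraction of the window length searched for the crossing.
    dt_threshold_s
        Threshold for the "pixels above" retention count (default 10 s).
    censor_policy
        ``assign_cap`` (default) or ``exclude`` for never-crossing pixels.
    log_floor_s
        Floor of the log10 display transform; ``None`` means one frame
        interval.
    """

    correlation_threshold: float = 0.5
    max_lag_fraction: float = 0.5
    dt_threshold_s: float = 10.0
    censor_policy: str = "assign_cap"
    log_floor_s: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")
        if not 0 < self.max_lag_fraction <= 1:
            raise ValueError("max_lag_fraction must be in (0, 1]")
        if not self.dt_threshold_s > 0:
            raise ValueError("dt_threshold_s must be > 0")
        if self.censor_policy not in ("assign_cap", "exclude"):
            raise ValueError("censor_policy must be 'assign_cap' or 'exclude'")

    def max_lag(self, n_samples: int) -> int:
        return max(1, min(n_samples - 1, int(self.max_lag_fraction * n_samples)))


@dataclass
class DTMap:
    """Per-pixel decorrelation times (s) for one acquisition window."""

    dt_s: np.ndarray  # (H, W), NaN outside mask / zero-variance pixels
    censored: np.ndarray  # (H, W) bool, ACF never crossed the threshold
    acquisition_index: int
    frame_interval_s: float
    max_lag: int

    @property
    def cap_s(self) -> float:
        return self.max_lag * self.frame_interval_s


@dataclass(frozen=True)
class DTSummary:
    mean_dt_s: float
    dt_variance_s2: float  # spatial sample variance across masked pixels
    n_pixels_above_threshold: int
    censored_fraction: float
    n_pixels: int


def zscore_series(values: np.ndarray) -> np.ndarray | None:
    """Z-score with sample SD (n−1); ``None`` marks a zero-variance input."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D series of at least 2 samples")
    sd = v.std(ddof=1)
    if sd == 0:
        return None
    return (v - v.mean()) / sd


def sample_acf(z: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample ACF normalized by the lag-0 sum.

    r(k) = sum_t z_t z_{t+k} / sum_t z_t^2 for k = 0..max_lag, which
    guarantees r(0) = 1 and |r(k)| <= 1.
    """
    z = np.asarray(z, dtype=np.float64)
    n = z.size
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < series length {n}")
    return _acf_matrix(z[None, :], max_lag)[0]


def _acf_matrix(z: np.ndarray, max_lag: int) -> np.ndarray:
    """Row-wise biased ACF of a (rows, T) matrix via FFT."""
    n = z.shape[1]
    nfft = 1
    while nfft < 2 * n:
        nfft <<= 1
    f = np.fft.rfft(z, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, : max_lag + 1]
    return acov / acov[:, :1]


def _interpolate_crossing(r: np.ndarray, threshold: float, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """First threshold crossing per ACF row, linearly interpolated.

    Returns ``(lag, censored)``: fractional crossing lags (NaN where
    censored) and the censor flags.
    """
    below = r[:, 1:] <= threshold  # lags 1..max_lag
    any_cross = below.any(axis=1)
    k = below.argmax(axis=1) + 1  # first lag at/below threshold
    k = np.where(any_cross, k, max_lag)
    rows = np.arange(r.shape[0])
    r_hi = r[rows, k - 1]
    r_lo = r[rows, k]
    denom = r_hi - r_lo
    frac = np.where(denom > 0, (r_hi - threshold) / np.where(denom > 0, denom, 1.0), 0.0)
    lag = (k - 1) + frac
    lag = np.where(any_cross, lag, np.nan)
    return lag, ~any_cross


def decorrelation_time(
    values: np.ndarray,
    frame_interval_s: float,
    config: DTConfig | None = None,
) -> tuple[float, bool]:
    """Decorrelation time of one pixel series.

    Returns ``(dt_s, censored)``; ``dt_s`` is NaN for zero-variance
    input, and for censored pixels follows the configured policy.
    """
    config = config or DTConfig()
    v = np.asarray(values, dtype=np.float64)
    if v.size < 4:
        raise ValueError("need at least 4 samples")
    z = zscore_series(v)
    if z is None:
        return float("nan"), False
    max_lag = config.max_lag(v.size)
    r = _acf_matrix(z[None, :], max_lag)
    lag, censored = _interpolate_crossing(r, config.correlation_threshold, max_lag)
    if censored[0]:
        dt = max_lag * frame_interval_s if config.censor_policy == "assign_cap" else float("nan")
        return dt, True
    return float(lag[0] * frame_interval_s), False


def dt_map(loop: CineLoop, mask: np.ndarray, config: DTConfig | None = None) -> DTMap:
    """Decorrelation-time image of one acquisition over the organ mask."""
    config = config or DTConfig()
    mask = np.asarray(mask).astype(bool)
    if mask.shape != loop.frame_shape:
        raise ValueError("mask shape does not match the cine frames")
    if not np.any(mask):
        raise ValueError("organ mask is empty")
    n_t = loop.n_frames
    if n_t < 4:
        raise ValueError("need at least 4 frames per acquisition")
    max_lag = config.max_lag(n_t)

    pix = loop.frames[:, mask].T.astype(np.float64)  # (Npx, T)
    sd = pix.std(axis=1, ddof=1)
    valid = sd > 0
    dt_flat = np.full(pix.shape[0], np.nan)
    cen_flat = np.zeros(pix.shape[0], dtype=bool)
    if np.any(valid):
        z = (pix[valid] - pix[valid].mean(axis=1, keepdims=True)) / sd[valid, None]
        r = _acf_matrix(z, max_lag)
        lag, censored = _interpolate_crossing(r, config.correlation_threshold, max_lag)
        dt = lag * loop.frame_interval_s
        if config.censor_policy == "assign_cap":
            dt = np.where(censored, max_lag * loop.frame_interval_s, dt)
        dt_flat[valid] = dt
        cen_flat[valid] = censored

    dt_img = np.full(mask.shape, np.nan)
    cen_img = np.zeros(mask.shape, dtype=bool)
    dt_img[mask] = dt_flat
    cen_img[mask] = cen_flat
    return DTMap(
        dt_s=dt_img,
        censored=cen_img,
        acquisition_index=loop.acquisition_index,
        frame_interval_s=loop.frame_interval_s,
        max_lag=max_lag,
    )


def dt_summary(dtm: DTMap, config: DTConfig | None = None) -> DTSummary:
    """Histogram metrics of one DT map: mean, spatial variance, counts.

    Under ``assign_cap`` censored pixels enter at the cap value; under
    ``exclude`` they are dropped from all three metrics.
    """
    config = config or DTConfig()
    finite = np.isfinite(dtm.dt_s)
    vals = dtm.dt_s[finite]
    n_censored = int(dtm.censored.sum())
    if config.censor_policy == "exclude":
        # censored pixels carry NaN under this policy and are already out
        n_valid = vals.size + n_censored
    else:
        n_valid = vals.size  # censored pixels sit at the cap value
    if vals.size < 2:
        raise ValueError("need at least 2 finite DT pixels")
    return DTSummary(
        mean_dt_s=float(vals.mean()),
        dt_variance_s2=float(np.var(vals, ddof=1)),
        n_pixels_above_threshold=int((vals > config.dt_threshold_s).sum()),
        censored_fraction=float(n_censored) / float(n_valid) if n_valid else 0.0,
        n_pixels=int(vals.size),
    )


def log_dt_map(dtm: DTMap, config: DTConfig | None = None) -> np.ndarray:
    """log10-transformed DT display map; missing stays missing."""
    config = config or DTConfig()
    floor = config.log_floor_s if config.log_floor_s is not None else dtm.frame_interval_s
    out = np.full(dtm.dt_s.shape, np.nan)
    finite = np.isfinite(dtm.dt_s)
    out[finite] = np.log10(np.maximum(dtm.dt_s[finite], floor))
    return out


def theoretical_ar1_dt(rho: float, frame_interval_s: float, threshold: float = 0.5) -> float:
    """Analytic decorrelation time of an AR(1) process: the lag where
    rho^k = threshold, in seconds."""
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    return float(np.log(threshold) / np.log(rho) * frame_interval_s)
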