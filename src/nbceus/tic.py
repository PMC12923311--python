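"""Time–intensity-curve (TIC) feature extraction and parametric mapping.

For a pixel or whole-organ TIC the package computes the standard bolus
kinetics descriptors:

* **TTP** — time-to-peak, seconds from the first sample to the (smoothed)
  maximum, ties broken by earliest occurrence;
* **PI** — peak intensity, the smoothed maximum;
* **AUC** — area under the curve by the trapezoidal rule on the
  *unsmoothed* samples;
* **AUrC / AUfC** — area under the rising limb (start→peak, inflow) and
  the falling limb (peak→end, washout/retention).  The peak sample
  belongs to both limbs, so AUrC + AUfC = AUC exactly.

Smoothing affects only peak location and PI, never the integrals, so
AUC is independent of the smoothing window.  Trapezoids are not drawn
across gaps between non-contiguous acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .datatypes import TIC, AcquisitionSeries

__all__ = [
    "TICFeatures",
    "ParametricMaps",
    "MapHistogramSummary",
    "whole_organ_tic",
    "smooth_tic",
    "tic_features",
    "parametric_maps",
    "map_histogram",
]

FEATURE_NAMES = ("ttp_s", "pi", "auc", "aurc", "aufc")


@dataclass(frozen=True)
class TICFeatures:
    ttp_s: float
    pi: float
    auc: float
    aurc: float
    aufc: float


@dataclass
class ParametricMaps:
    """Per-pixel TIC feature images; NaN outside the organ mask."""

    ttp_s: np.ndarray
    pi: np.ndarray
    auc: np.ndarray
    aurc: np.ndarray
    aufc: np.ndarray
    mask: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in FEATURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self):
        return ((name, getattr(self, name)) for name in FEATURE_NAMES)


@dataclass
class MapHistogramSummary:
    mean: float
    variance: float
    skewness: float  # moment-based g1; NaN for zero-variance maps
    percentiles: dict  # {5, 25, 50, 75, 95} -> value
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int


def concatenated_series(series: AcquisitionSeries) -> tuple[np.ndarray, np.ndarray]:
    """All acquisitions on one absolute time axis.

    Returns ``(times_s, stack)`` where stack is (T_total, H, W).
    """
    times = np.concatenate([loop.times_s for loop in series.loops])
    stack = np.concatenate([loop.frames for loop in series.loops], axis=0)
    return times, stack


def whole_organ_tic(series: AcquisitionSeries) -> TIC:
    """Mean masked intensity per frame, all acquisitions concatenated."""
    if not np.any(series.mask):
        raise ValueError("organ mask is empty")
    times, stack = concatenated_series(series)
    values = stack[:, series.mask].mean(axis=1)
    return TIC(times_s=times, values=values)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation, along axis 0.

    Near the boundaries the window shrinks to the samples available, so
    the output length equals the input length.
    """
    if window == 1:
        return values.astype(np.float64, copy=True)
    kernel = np.ones(window)
    if values.ndim == 1:
        sums = np.convolve(values, kernel, mode="same")
        counts = np.convolve(np.ones(values.shape[0]), kernel, mode="same")
    else:
        from scipy import ndimage

        sums = ndimage.convolve1d(values, kernel, axis=0, mode="constant", cval=0.0)
        counts = np.convolve(np.ones(values.shape[0]), kernel, mode="same")
        counts = counts.reshape((-1,) + (1,) * (values.ndim - 1))
    return sums / counts


def _check_window(window: int, n: int) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds series length {n}")


def smooth_tic(tic: TIC, window: int = 5) -> TIC:
    """Centered moving average of a TIC; ``window=1`` is the identity."""
    _check_window(window, len(tic))
    return TIC(times_s=tic.times_s.copy(), values=_moving_average(tic.values, window))


def _gap_weights(times: np.ndarray) -> np.ndarray:
    """Per-interval trapezoid inclusion weights.

    An interval much longer than the typical frame spacing is a gap
    between non-contiguous acquisitions; no trapezoid is drawn there.
    """
    dt = np.diff(times)
    typical = np.median(dt)
    return np.where(dt <= 2.0 * typical, 1.0, 0.0)


def _trapezoid_matrix(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative trapezoidal integral along axis 0, honouring gaps.

    Returns ``(cumulative, total)`` where cumulative[k] is the integral
    from the first sample up to sample k.
    """
    dt = np.diff(times) * _gap_weights(times)
    seg = 0.5 * (values[1:] + values[:-1]) * dt.reshape((-1,) + (1,) * (values.ndim - 1))
    cum = np.concatenate([np.zeros((1,) + values.shape[1:]), np.cumsum(seg, axis=0)], axis=0)
    return cum, cum[-1]


def tic_features(tic: TIC, smooth_window: int = 5) -> TICFeatures:
    """TTP, PI and the AUC/AUrC/AUfC decomposition of one TIC."""
    n = len(tic)
    _check_window(smooth_window, n)
    smoothed = _moving_average(tic.values, smooth_window)
    peak = int(np.argmax(smoothed))  # first occurrence on ties
    cum, total = _trapezoid_matrix(tic.times_s, tic.values)
    return TICFeatures(
        ttp_s=float(tic.times_s[peak] - tic.times_s[0]),
        pi=float(smoothed[peak]),
        auc=float(total),
        aurc=float(cum[peak]),
        aufc=float(total - cum[peak]),
    )


def _apply_baseline(values: np.ndarray, baseline_frames: int) -> np.ndarray:
    """Subtract the mean of the first N frames, floored at zero."""
    if baseline_frames <= 0:
        return values
    base = values[:baseline_frames].mean(axis=0)
    return np.clip(values - base, 0.0, None)


def parametric_maps(
    series: AcquisitionSeries,
    smooth_window: int = 5,
    baseline_frames: int = 0,
) -> ParametricMaps:
    """Per-pixel TIC features over the organ mask, vectorized.

    Pixels outside the mask are NaN.  Identical to applying
    :func:`tic_features` to each masked pixel's concatenated TIC.
    """
    mask = series.mask
    if not np.any(mask):
        raise ValueError("organ mask is empty")
    times, stack = concatenated_series(series)
    _check_window(smooth_window, times.size)

    pix = stack[:, mask].astype(np.float64)  # (T, Npx)
    pix = _apply_baseline(pix, baseline_frames)
    smoothed = _moving_average(pix, smooth_window)
    peak = np.argmax(smoothed, axis=0)  # first occurrence per pixel
    cum, total = _trapezoid_matrix(times, pix)
    idx = np.arange(pix.shape[1])
    aurc = cum[peak, idx]

    def as_map(flat: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, np.nan)
        out[mask] = flat
        return out

    return ParametricMaps(
        ttp_s=as_map(times[peak] - times[0]),
        pi=as_map(smoothed[peak, idx]),
        auc=as_map(total),
        aurc=as_map(aurc),
        aufc=as_map(total - aurc),
        mask=mask.copy(),
    )


def map_histogram(map_2d: np.ndarray, mask: np.ndarray | None = None, n_bins: int = 32) -> MapHistogramSummary:
    """Moments, percentiles and histogram of the masked finite map values.

    Skewness is the moment-based sample coefficient g1 (no bias
    correction); variance uses the n−1 denominator.  A constant map has
    zero variance and undefined (NaN) skewness.
    """
    vals = np.asarray(map_2d, dtype=float)
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)]
    vals = np.ravel(vals)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite masked values")
    variance = float(np.var(vals, ddof=1))
    skew = float(sstats.skew(vals, bias=True)) if variance > 0 else float("nan")
    counts, edges = np.histogram(vals, bins=n_bins)
    pcts = {p: float(np.percentile(vals, p)) for p in (5, 25, 50, 75, 95)}
    return MapHistogramSummary(
        mean=float(vals.mean()),
        variance=variance,
        skewness=skew,
        percentiles=pcts,
        bin_edges=edges,
        counts=counts,
        n=int(vals.size),
    )
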