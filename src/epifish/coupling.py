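"""Electrophysiology-imaging coupling: aligned power and x-correlation maps.

The log-RMS power series is linearly interpolated at the mean time point
of each imaging frame; pixelwise and trace-wise cross-correlations then
localize the sources of high-frequency LFP transients.

Lag convention: the correlogram value at lag ``l`` pairs the calcium
signal at time ``t`` with power at ``t - l``, so a *negative* lag means
calcium leads power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from epifish.calcium_dff import DffStack
from epifish.lfp_power import BandPowerSeries

__all__ = [
    "AlignedPower",
    "XCorrMap",
    "align_power",
    "xcorr_trace",
    "xcorr_map",
    "estimate_L",
    "windowed_maps",
]


@dataclass(frozen=True)
class AlignedPower:
    """Log-RMS power interpolated at frame mean times."""

    values: np.ndarray
    frame_times: np.ndarray
    extrapolated: np.ndarray = field(repr=False)  # bool per frame

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class XCorrMap:
    """Pixelwise lag-summed cross-correlation with the LFP power."""

    values: np.ndarray                 # (y, x)
    L: int                             # lag half-width, frames
    normalized: bool                   # True if scaled to map max = 1
    window: tuple[int, int] | None = None  # frame interval used
    raw_sum: bool = False


def align_power(series: BandPowerSeries,
                frame_times: np.ndarray) -> AlignedPower:
    """Linearly interpolate log power at the frame mean times.

    Frame times outside the power-series span take the nearest edge
    value and are flagged.
    """
    if series.times.size == 0:
        raise ValueError("empty power series")
    ft = np.asarray(frame_times, dtype=float)
    values = np.interp(ft, series.times, series.log_power)
    extrapolated = (ft < series.times[0]) | (ft > series.times[-1])
    return AlignedPower(values=values, frame_times=ft,
                        extrapolated=extrapolated)


def _zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    mu = np.nanmean(x, axis=axis, keepdims=True)
    sd = np.nanstd(x, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (x - mu) / sd


def xcorr_trace(trace: np.ndarray, power: np.ndarray,
                max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of two equal-length series at each lag.

    Returns ``(lags, r)`` for lags in [-max_lag, max_lag]; at lag ``l``
    the pair is ``(trace[t], power[t - l])`` over the truncated overlap
    (no wrap-around), so negative lags mean the trace leads the power.
    """
    a = np.asarray(trace, dtype=float)
    b = np.asarray(power, dtype=float)
    if a.size != b.size:
        raise ValueError("series lengths differ")
    if np.nanstd(a) == 0 or np.nanstd(b) == 0:
        raise ValueError("zero-variance input")
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size)
    for i, l in enumerate(lags):
        if l >= 0:
            x, y = a[l:], b[:b.size - l]
        else:
            x, y = a[:a.size + l], b[-l:]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            r[i] = np.nan
            continue
        r[i] = np.corrcoef(x, y)[0, 1]
    return lags, r


def xcorr_map(dff: DffStack, power: AlignedPower, L: int,
              window: tuple[int, int] | None = None,
              normalize: bool = True, raw_sum: bool = False) -> XCorrMap:
    """Pixelwise cross-correlation of dF/F0 with the aligned log power.

    For each pixel, lag-l correlations between the (z-scored) power and
    dF/F0 are summed over |l| <= L and divided by the number of lags, so
    the result is a bounded correlation-like quantity. ``raw_sum=True``
    skips z-scoring and per-term normalization (unbounded variant).
    ``normalize=True`` additionally scales the map to a maximum of 1.
    """
    if dff.n_frames != power.n_frames:
        raise ValueError("frame counts differ")
    if L < 0:
        raise ValueError("L must be >= 0")
    if window is None:
        lo, hi = 0, dff.n_frames
    else:
        lo, hi = window
    if hi - lo < 2 * L + 1:
        raise ValueError("window shorter than 2L+1 frames")
    d = dff.dff[lo:hi].reshape(hi - lo, -1)
    p = power.values[lo:hi]
    if not raw_sum:
        d = _zscore(d, axis=0)
        p = _zscore(p)
    t = hi - lo
    acc = np.zeros(d.shape[1])
    for l in range(-L, L + 1):
        if l >= 0:
            x, y = d[l:], p[:t - l]
        else:
            x, y = d[:t + l], p[-l:]
        term = np.nansum(x * y[:, None], axis=0)
        if not raw_sum:
            term = term / x.shape[0]
        acc += term
    if not raw_sum:
        acc /= (2 * L + 1)
    values = acc.reshape(dff.dff.shape[1:])
    values = np.where(dff.mask, values, np.nan)
    if normalize:
        vmax = np.nanmax(np.abs(values))
        if vmax > 0:
            values = values / vmax
    return XCorrMap(values=values, L=L, normalized=normalize,
                    window=None if window is None else (lo, hi),
                    raw_sum=raw_sum)


def estimate_L(dff: DffStack, power: AlignedPower, max_lag: int = 40,
               default: int = 4) -> tuple[int, bool]:
    """Lag half-width of the central cross-correlation peak.

    L is the half-width at half maximum of the central positive peak of
    the correlogram between the whole-field mean dF/F0 and the aligned
    power, floored at 1 frame. Returns ``(L, ok)``; when no positive
    central peak exists, ``(default, False)``.
    """
    mean_trace = np.nanmean(dff.dff[:, dff.mask], axis=1)
    lags, r = xcorr_trace(mean_trace, power.values, max_lag)
    finite = np.isfinite(r)
    if not finite.any() or np.nanmax(r) <= 0:
        return default, False
    peak_idx = int(np.nanargmax(r))
    if r[peak_idx] <= 0:
        return default, False
    half = r[peak_idx] / 2.0
    left = 0
    i = peak_idx
    while i - 1 >= 0 and np.isfinite(r[i - 1]) and r[i - 1] >= half:
        i -= 1
        left += 1
    right = 0
    i = peak_idx
    while i + 1 < r.size and np.isfinite(r[i + 1]) and r[i + 1] >= half:
        i += 1
        right += 1
    width = max(1, int(round((left + right) / 2.0)))
    return width, True


def windowed_maps(dff: DffStack, power: AlignedPower, L: int,
                  intervals: list[tuple[int, int]],
                  normalize: bool = True) -> list[XCorrMap]:
    """One self-normalized map per (disjoint) frame interval."""
    ivs = sorted(intervals)
    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
        if b0 < a1:
            raise ValueError("intervals overlap")
    return [xcorr_map(dff, power, L, window=iv, normalize=normalize)
            for iv in ivs]
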