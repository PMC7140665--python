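"""Band-limited sliding RMS power of the LFP and its mode decomposition.

The log10 RMS power distribution of a band-passed LFP is split into a
Gaussian bulk (Main Mode, MM) and a right tail of high-power windows
(Secondary Mode, SM). The difference between the SM and MM means
(``delta_sm_mm``) and the MM mean quantify epileptiform activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from epifish.modefit import trim_normal_fit

__all__ = [
    "LFPTrace",
    "BandPowerSeries",
    "PowerModeFit",
    "bandpass",
    "sliding_log_rms",
    "fit_power_modes",
    "mode_metrics",
    "sm_event_times",
]


@dataclass(frozen=True)
class LFPTrace:
    """Single-channel LFP voltage trace.

    Attributes
    ----------
    samples:
        Voltage samples in microvolts.
    sampling_rate:
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.samples.size == 0:
            raise ValueError("zero-length trace")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class BandPowerSeries:
    """Sliding-window log10 RMS power of a band-passed trace."""

    times: np.ndarray          # window centers, s
    log_power: np.ndarray      # log10(uV RMS) per window
    band: tuple[float, float]  # Hz
    window: float              # s
    step: float                # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "log_power",
                           np.asarray(self.log_power, dtype=float))
        if self.times.shape != self.log_power.shape:
            raise ValueError("times and log_power must have equal length")


@dataclass(frozen=True)
class PowerModeFit:
    """Main-/Secondary-Mode decomposition of a log-power distribution."""

    mm_mean: float
    mm_sd: float
    sm_indices: np.ndarray = field(repr=False)
    sm_mean: float
    delta_sm_mm: float
    n_iterations: int
    converged: bool
    sm_empty: bool
    k_sd: float = 2.0

    @property
    def threshold(self) -> float:
        """SM threshold in log-power units: mm_mean + k_sd * mm_sd."""
        return self.mm_mean + self.k_sd * self.mm_sd


def bandpass(trace: LFPTrace, band: tuple[float, float],
             order: int = 4) -> LFPTrace:
    """Zero-phase Butterworth band-pass of an LFP trace.

    A 4th-order filter applied forward-backward (zero phase), so burst
    timing is preserved for downstream cross-correlation.
    """
    low, high = band
    nyq = trace.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=trace.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return LFPTrace(samples=filtered, sampling_rate=trace.sampling_rate)


def sliding_log_rms(trace: LFPTrace, window: float = 0.25,
                    step: float = 0.05) -> BandPowerSeries:
    """Log10 RMS power in a sliding window.

    ``log_power[k]`` is the log10 RMS of samples in
    ``[k*step, k*step + window)`` seconds; window count is
    ``floor((N - window*rate) / (step*rate)) + 1``.
    """
    rate = trace.sampling_rate
    wlen = int(round(window * rate))
    slen = int(round(step * rate))
    if wlen < 2:
        raise ValueError("window too short: needs >= 2 samples")
    if slen < 1 or slen > wlen:
        raise ValueError("step must satisfy 0 < step <= window")
    n = trace.samples.size
    if n < wlen:
        raise ValueError("trace shorter than one window")
    n_win = (n - wlen) // slen + 1
    starts = np.arange(n_win) * slen
    idx = starts[:, None] + np.arange(wlen)[None, :]
    seg = trace.samples[idx]
    rms = np.sqrt(np.mean(seg * seg, axis=1))
    # guard log of exactly-zero windows
    tiny = np.finfo(float).tiny
    log_power = np.log10(np.maximum(rms, tiny))
    times = (starts + wlen / 2.0) / rate
    return BandPowerSeries(times=times, log_power=log_power,
                           band=(0.0, rate / 2.0), window=window, step=step)


def band_log_rms(trace: LFPTrace, band: tuple[float, float] = (30.0, 95.0),
                 window: float = 0.25, step: float = 0.05) -> BandPowerSeries:
    """Convenience: band-pass then sliding log-RMS, recording the band."""
    series = sliding_log_rms(bandpass(trace, band), window=window, step=step)
    return BandPowerSeries(times=series.times, log_power=series.log_power,
                           band=band, window=window, step=step)


def fit_power_modes(series: BandPowerSeries, k_sd: float = 2.0,
                    tol: float = 0.05, max_iter: int = 100,
                    robust: bool = False) -> PowerModeFit:
    """Decompose a log-power distribution into Main and Secondary Modes.

    Iteratively fits a normal distribution to the log powers, removing
    right-tail samples beyond ``mean + k_sd*sd`` until mean and median of
    the residual population converge. The final moments define the Main
    Mode; the Secondary Mode is every *original* sample above the final
    threshold.
    """
    x = series.log_power
    if x.size < 50:
        raise ValueError("need at least 50 windows for a mode fit")
    fit = trim_normal_fit(x, k_sd=k_sd, tol=tol, max_iter=max_iter,
                          robust=robust)
    thr = fit.mean + k_sd * fit.sd
    sm_idx = np.flatnonzero(x > thr)
    sm_empty = sm_idx.size == 0
    sm_mean = float(np.mean(x[sm_idx])) if not sm_empty else fit.mean
    return PowerModeFit(
        mm_mean=fit.mean,
        mm_sd=fit.sd,
        sm_indices=sm_idx,
        sm_mean=sm_mean,
        delta_sm_mm=0.0 if sm_empty else sm_mean - fit.mean,
        n_iterations=fit.n_iterations,
        converged=fit.converged,
        sm_empty=sm_empty,
        k_sd=k_sd,
    )


def mode_metrics(fit: PowerModeFit) -> dict[str, float]:
    """Scalar metrics for group comparison."""
    return {
        "mm_mean": fit.mm_mean,
        "mm_sd": fit.mm_sd,
        "sm_mean": fit.sm_mean,
        "delta_sm_mm": fit.delta_sm_mm,
        "sm_count": int(fit.sm_indices.size),
        "sm_empty": bool(fit.sm_empty),
    }


def sm_event_times(series: BandPowerSeries, fit: PowerModeFit,
                   min_separation: float = 0.0) -> np.ndarray:
    """Times of upward crossings of the SM threshold, in seconds.

    Crossings closer than ``min_separation`` to the previous accepted
    event are merged into it.
    """
    above = series.log_power > fit.threshold
    up = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    times = series.times[up]
    if min_separation > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= min_separation:
                kept.append(t)
        times = np.asarray(kept)
    return times
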