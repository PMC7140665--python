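"""Iterative trimmed-Gaussian fit of the bulk ("main mode") of a sample.

The same routine backs the LFP log-power mode decomposition and the
per-pixel baseline estimation used to binarize dF/F0 stacks: fit a normal
distribution by sample moments, drop samples on the right tail beyond
``mean + k_sd * sd``, and repeat until mean and median of the surviving
population agree to within ``tol * sd`` (or nothing more is removed, or
``max_iter`` is reached).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrimFit", "trim_normal_fit", "trim_normal_fit_stack"]


@dataclass(frozen=True)
class TrimFit:
    """Result of the iterative right-tail trim on a 1-D sample."""

    mean: float
    sd: float
    median: float
    kept: np.ndarray  # boolean mask over the original samples
    n_iterations: int
    converged: bool


def _moments(x: np.ndarray, robust: bool) -> tuple[float, float, float]:
    med = float(np.median(x))
    if robust:
        # median / scaled MAD alternative (not the default path)
        mad = float(np.median(np.abs(x - med)))
        return med, 1.4826 * mad, med
    return float(np.mean(x)), float(np.std(x, ddof=1)), med


def trim_normal_fit(
    samples: np.ndarray,
    k_sd: float = 2.0,
    tol: float = 0.05,
    max_iter: int = 100,
    robust: bool = False,
) -> TrimFit:
    """Fit the main mode of ``samples`` by iterative right-tail removal.

    Parameters
    ----------
    samples:
        1-D array of finite values.
    k_sd:
        Trim threshold in standard deviations above the current mean.
    tol:
        Convergence criterion: ``|mean - median| < tol * sd``.
    max_iter:
        Iteration cap.
    robust:
        If True, use median / scaled-MAD in place of mean / sample SD.

    Raises
    ------
    ValueError
        On empty input, non-finite values, or zero variance.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: all samples identical")

    kept = np.ones(x.size, dtype=bool)
    mean, sd, med = _moments(x, robust)
    converged = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        if sd == 0:
            raise ValueError("zero variance reached while trimming")
        if abs(mean - med) < tol * sd:
            converged = True
            break
        drop = kept & (x > mean + k_sd * sd)
        if not drop.any():
            converged = True
            break
        kept &= ~drop
        mean, sd, med = _moments(x[kept], robust)
    return TrimFit(mean=mean, sd=sd, median=med, kept=kept,
                   n_iterations=n_it, converged=converged)


def trim_normal_fit_stack(
    samples: np.ndarray,
    k_sd: float = 2.0,
    tol: float = 0.05,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized trim fit along axis 0 of a (n_samples, n_series) array.

    Returns ``(mean, sd, valid)`` per series. Series with zero variance are
    flagged invalid (NaN moments) instead of raising, so a whole imaging
    stack can be processed in one call.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (n_samples, n_series) array")
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples per series")

    work = x.copy()
    valid = np.ptp(x, axis=0) > 0
    work[:, ~valid] = np.nan
    active = valid.copy()

    mean = np.full(m, np.nan)
    sd = np.full(m, np.nan)
    with np.errstate(invalid="ignore"):
        for _ in range(max_iter):
            if not active.any():
                break
            mu = np.nanmean(work[:, active], axis=0)
            s = np.nanstd(work[:, active], axis=0, ddof=1)
            med = np.nanmedian(work[:, active], axis=0)
            mean[active] = mu
            sd[active] = s
            done = (np.abs(mu - med) < tol * s) | (s == 0)
            thr = mu + k_sd * s
            sub = work[:, active]
            drop = sub > thr[None, :]
            drop[:, done] = False
            removed = drop.any(axis=0)
            sub[drop] = np.nan
            work[:, active] = sub
            still = ~done & removed
            idx = np.flatnonzero(active)
            active[idx[~still]] = False
        if active.any():
            # hit max_iter: record the final moments
            mean[active] = np.nanmean(work[:, active], axis=0)
            sd[active] = np.nanstd(work[:, active], axis=0, ddof=1)
    valid &= sd > 0
    return mean, sd, valid
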