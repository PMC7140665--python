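"""Per-pixel dF/F0, skewness statistics, and statistical binarization.

Stacks are stored time-major, shape ``(t, y, x)``; exported coordinates
use 0-based ``(x=column, y=row, t=frame)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from epifish.modefit import trim_normal_fit_stack

__all__ = [
    "FluorescenceStack",
    "DffStack",
    "SkewnessMap",
    "BinaryStack",
    "preprocess",
    "compute_dff",
    "pearson_skewness",
    "skewness_map",
    "binarize",
    "temporal_persistence_filter",
    "spatial_support_filter",
]


@dataclass(frozen=True)
class FluorescenceStack:
    """Time-lapse fluorescence stack in raw counts, shape (t, y, x)."""

    pixels: np.ndarray
    frame_rate: float
    pixel_size: float = 1.0   # um per pixel
    dark_level: float = 0.0   # counts already subtracted, 0 if raw

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3:
            raise ValueError("pixels must be 3-D (t, y, x)")
        if px.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def frame_times(self) -> np.ndarray:
        """Mean exposure time of each frame, seconds: (i + 0.5) / rate."""
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate


@dataclass(frozen=True)
class DffStack:
    """Relative fluorescence fluctuation per pixel, shape (t, y, x).

    ``dff[t, y, x] = (f[t, y, x] - <f[y, x]>) / <f[y, x]>`` with the
    temporal mean ``<f>`` taken over the full recording. Pixels whose
    baseline is non-positive are masked (``mask`` True = usable).
    """

    dff: np.ndarray
    mask: np.ndarray = field(repr=False)
    frame_rate: float = 1.0
    pixel_size: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    def frame_times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate


@dataclass(frozen=True)
class SkewnessMap:
    """Per-pixel and pooled Pearson second skewness of dF/F0."""

    values: np.ndarray         # (y, x), NaN where masked
    pooled: float              # skewness of the pooled pixel distribution


@dataclass(frozen=True)
class BinaryStack:
    """Supra-threshold voxels after persistence and support filtering."""

    voxels: np.ndarray         # bool (t, y, x)
    k_sd: float
    min_frames: int
    min_neighbors: int
    frame_rate: float = 1.0
    pixel_size: float = 1.0


def preprocess(stack: FluorescenceStack, dark_level: float = 0.0,
               bin_factor: int = 2) -> FluorescenceStack:
    """Dark-subtract and block-average ``bin_factor x bin_factor``.

    Trailing rows/columns not divisible by the bin factor are dropped.
    A 512x512 acquisition becomes 256x256 at the default factor.
    """
    px = stack.pixels
    if dark_level > 0 and dark_level > px.mean(axis=0).min():
        raise ValueError(
            "dark_level exceeds the dimmest pixel mean; mis-set dark signal")
    px = px - dark_level
    if bin_factor > 1:
        t, h, w = px.shape
        h2, w2 = (h // bin_factor) * bin_factor, (w // bin_factor) * bin_factor
        px = px[:, :h2, :w2]
        px = px.reshape(t, h2 // bin_factor, bin_factor,
                        w2 // bin_factor, bin_factor).mean(axis=(2, 4))
    return FluorescenceStack(pixels=px, frame_rate=stack.frame_rate,
                             pixel_size=stack.pixel_size * bin_factor,
                             dark_level=dark_level)


def compute_dff(stack: FluorescenceStack, eps: float = 1e-9) -> DffStack:
    """Per-pixel dF/F0 against the global temporal-mean baseline."""
    f = stack.pixels
    f0 = f.mean(axis=0)
    if np.all(f0 <= eps):
        raise ValueError("all-zero stack: no baseline")
    mask = f0 > eps
    dff = np.zeros_like(f)
    np.divide(f - f0[None], f0[None], out=dff,
              where=mask[None])
    dff[:, ~mask] = np.nan
    return DffStack(dff=dff, mask=mask, frame_rate=stack.frame_rate,
                    pixel_size=stack.pixel_size)


def pearson_skewness(samples: np.ndarray) -> float:
    """Pearson's second skewness coefficient: 3 * (mean - median) / SD."""
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation")
    return 3.0 * (float(np.mean(x)) - float(np.median(x))) / sd


def skewness_map(dff: DffStack) -> SkewnessMap:
    """Per-pixel skewness over time plus the pooled whole-section value."""
    d = dff.dff
    mean = np.nanmean(d, axis=0)
    med = np.nanmedian(d, axis=0)
    sd = np.nanstd(d, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 3.0 * (mean - med) / sd
    values[~dff.mask] = np.nan
    values[sd == 0] = np.nan
    pooled = pearson_skewness(d[:, dff.mask])
    return SkewnessMap(values=values, pooled=pooled)


def temporal_persistence_filter(voxels: np.ndarray,
                                min_frames: int = 3) -> np.ndarray:
    """Delete positive runs shorter than ``min_frames`` along t."""
    b = np.asarray(voxels, dtype=bool)
    t = b.shape[0]
    run = np.zeros(b.shape, dtype=np.int32)
    acc = np.zeros(b.shape[1:], dtype=np.int32)
    for i in range(t):
        acc = np.where(b[i], acc + 1, 0)
        run[i] = acc
    out = np.zeros_like(b)
    length = np.zeros(b.shape[1:], dtype=np.int32)
    for i in range(t - 1, -1, -1):
        cont = b[i + 1] if i + 1 < t else np.zeros_like(b[i])
        length = np.where(b[i], np.where(cont, length, run[i]), 0)
        out[i] = b[i] & (length >= min_frames)
    return out


_NEIGHBOR_KERNEL = np.array([[[1, 1, 1], [1, 0, 1], [1, 1, 1]]])


def spatial_support_filter(voxels: np.ndarray,
                           min_neighbors: int = 2) -> np.ndarray:
    """Keep positive pixels with >= ``min_neighbors`` positive 8-neighbors.

    Applied per frame and iterated to a fixed point so the operation is
    idempotent; isolated speckle and thin filaments are pruned, compact
    domains are untouched.
    """
    b = np.asarray(voxels, dtype=bool)
    while True:
        counts = ndimage.convolve(b.astype(np.uint8), _NEIGHBOR_KERNEL,
                                  mode="constant", cval=0)
        keep = b & (counts >= min_neighbors)
        if np.array_equal(keep, b):
            return keep
        b = keep


def binarize(dff: DffStack, k_sd: float = 2.0, min_frames: int = 3,
             min_neighbors: int = 2, tol: float = 0.05,
             max_iter: int = 100) -> BinaryStack:
    """Statistically threshold a dF/F0 stack into active/inactive voxels.

    Each pixel's baseline Gaussian is estimated with the same
    iterative-trim fit used for the LFP power modes; samples beyond
    ``mean + k_sd*sd`` are set to 1. The binary stack is then cleaned by
    the temporal persistence filter (runs >= ``min_frames``) followed by
    the spatial support filter (>= ``min_neighbors`` positive 8-neighbors
    in the same frame). Zero-variance pixels are masked.
    """
    d = dff.dff
    t = d.shape[0]
    flat = d.reshape(t, -1)
    mean, sd, valid = trim_normal_fit_stack(flat, k_sd=k_sd, tol=tol,
                                            max_iter=max_iter)
    thr = mean + k_sd * sd
    with np.errstate(invalid="ignore"):
        raw = (flat > thr[None, :]) & valid[None, :]
    raw = raw.reshape(d.shape)
    raw[:, ~dff.mask] = False
    clean = temporal_persistence_filter(raw, min_frames=min_frames)
    clean = spatial_support_filter(clean, min_neighbors=min_neighbors)
    return BinaryStack(voxels=clean, k_sd=k_sd, min_frames=min_frames,
                       min_neighbors=min_neighbors,
                       frame_rate=dff.frame_rate, pixel_size=dff.pixel_size)
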