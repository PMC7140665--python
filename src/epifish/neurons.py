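"""Single-neuron detection, PCA, and Ep / pre-Ep population mapping.

Cell bodies are found by normalized cross-correlation of the median
projection with donut-shaped templates; each neuron's dF/F0 trace feeds
a PCA whose components are matched against the LFP log-RMS power: the
component with the highest zero-lag correlation is the epileptiform (Ep)
descriptor, the one with a positive correlogram peak at the negative lag
closest to zero is the pre-epileptiform (pre-Ep) descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max
from skimage.transform import SimilarityTransform, warp
from sklearn.decomposition import PCA

from epifish.calcium_dff import DffStack, FluorescenceStack
from epifish.coupling import AlignedPower, xcorr_trace

__all__ = [
    "NeuronROI",
    "PCADecomposition",
    "EpClassification",
    "LoadingMap",
    "donut_template",
    "detect_neurons",
    "extract_traces",
    "run_pca",
    "select_components",
    "event_correlograms",
    "loading_maps",
    "collective_map",
]


@dataclass(frozen=True)
class NeuronROI:
    """A circular single-neuron ROI and its dF/F0 trace."""

    center: tuple[int, int]       # (x, y), px
    radius: int
    trace: np.ndarray = field(repr=False)
    score: float = np.nan


@dataclass(frozen=True)
class PCADecomposition:
    """PCA of z-scored neuron traces (neurons = variables, time = samples)."""

    scores: np.ndarray            # (t, n_pc) component time courses
    loadings: np.ndarray          # (n_neurons, n_pc)
    explained_variance: np.ndarray  # fractions, descending
    centers: list[tuple[int, int]]
    dropped: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class EpClassification:
    """Selected Ep / pre-Ep components and their correlograms."""

    ep_pc: int
    pre_ep_pc: int | None
    lags: np.ndarray
    correlograms: np.ndarray      # (n_pc, n_lags)
    ep_zero_lag: float
    pre_ep_peak_lag: int | None
    pre_ep_defined: bool


@dataclass(frozen=True)
class LoadingMap:
    """Normalized loadings of one class placed at neuron centers."""

    values: np.ndarray            # (y, x), 0 off-neuron
    neuron_ids: np.ndarray        # indices into the PCA neuron list
    normalized_loadings: np.ndarray
    profile_bins: np.ndarray      # rostro-caudal bin centers (px)
    profile: np.ndarray           # summed normalized loading per bin
    empty: bool = False           # True when exclusions removed every neuron


def donut_template(size: int, inner_fraction: float = 0.4,
                   center_level: float = 0.3) -> np.ndarray:
    """Zero-mean donut filter: bright annulus, dimmer center, zero surround.

    ``size`` is the outer diameter in pixels; the template canvas is the
    next odd width so the peak is centered on a pixel.
    """
    canvas = size + 1 if size % 2 == 0 else size
    c = canvas // 2
    yy, xx = np.mgrid[:canvas, :canvas]
    r = np.hypot(yy - c, xx - c)
    r_out = size / 2.0
    r_in = inner_fraction * r_out
    tpl = np.zeros((canvas, canvas))
    tpl[(r > r_in) & (r <= r_out)] = 1.0
    tpl[r <= r_in] = center_level
    tpl -= tpl.mean()
    return tpl


def detect_neurons(stack: FluorescenceStack | np.ndarray,
                   template_sizes: tuple[int, ...] = (10, 7),
                   min_distance: int = 5,
                   score_threshold: float = 0.3,
                   min_contrast: float = 0.5) -> list[tuple[int, int, float]]:
    """Locate neuron somata on the median projection.

    The median projection is denoised with a 3x3 median filter and
    matched (normalized cross-correlation) against donut templates at
    each size; local maxima above ``score_threshold`` are accepted
    greedily in descending score with a ``min_distance`` exclusion zone,
    merging duplicates across template sizes. Because NCC is
    contrast-invariant, matches in near-flat areas are rejected unless
    the local SD under the template footprint is at least
    ``min_contrast`` times the image SD.

    Returns a list of ``(x, y, score)`` tuples.
    """
    pixels = stack.pixels if isinstance(stack, FluorescenceStack) else stack
    if pixels.ndim == 3:
        if pixels.shape[0] < 10:
            raise ValueError("need >= 10 frames for a stable projection")
        proj = np.median(pixels, axis=0)
    else:
        proj = np.asarray(pixels, dtype=float)
    proj = ndimage.median_filter(proj, size=3)
    global_sd = float(proj.std())
    candidates: list[tuple[float, int, int]] = []
    for size in template_sizes:
        tpl = donut_template(size)
        score = match_template(proj, tpl, pad_input=True)
        local_mean = ndimage.uniform_filter(proj, size=tpl.shape[0])
        local_sq = ndimage.uniform_filter(proj ** 2, size=tpl.shape[0])
        local_sd = np.sqrt(np.maximum(local_sq - local_mean ** 2, 0.0))
        peaks = peak_local_max(score, min_distance=min_distance,
                               threshold_abs=score_threshold,
                               exclude_border=False)
        for y, x in peaks:
            if local_sd[y, x] < min_contrast * global_sd:
                continue
            candidates.append((float(score[y, x]), int(x), int(y)))
    candidates.sort(reverse=True)
    accepted: list[tuple[int, int, float]] = []
    for s, x, y in candidates:
        if all((x - ax) ** 2 + (y - ay) ** 2 >= min_distance ** 2
               for ax, ay, _ in accepted):
            accepted.append((x, y, s))
    return accepted


def _disk_offsets(radius: int) -> np.ndarray:
    rng = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    keep = dy ** 2 + dx ** 2 <= radius ** 2
    return np.stack([dy[keep], dx[keep]], axis=1)


def extract_traces(dff: DffStack, centers: list[tuple[int, int]],
                   radius: int = 3) -> tuple[list[NeuronROI], list[int]]:
    """Mean dF/F0 over a discrete disk around each center.

    Centers too close to the image edge (margin < radius) are dropped;
    the indices of dropped centers are returned alongside the ROIs.
    """
    if not centers:
        raise ValueError("empty center list")
    offsets = _disk_offsets(radius)
    h, w = dff.dff.shape[1:]
    rois: list[NeuronROI] = []
    dropped: list[int] = []
    for i, (x, y) in enumerate(centers):
        if not (radius <= x < w - radius and radius <= y < h - radius):
            dropped.append(i)
            continue
        ys = y + offsets[:, 0]
        xs = x + offsets[:, 1]
        trace = np.nanmean(dff.dff[:, ys, xs], axis=1)
        rois.append(NeuronROI(center=(int(x), int(y)), radius=radius,
                              trace=trace))
    return rois, dropped


def run_pca(rois: list[NeuronROI], n_pc: int = 10,
            power: AlignedPower | None = None,
            max_lag: int = 20) -> PCADecomposition:
    """PCA of the neuron x time matrix with unit-SD traces.

    Neurons are variables and time points samples. Zero-variance neurons
    are dropped (and reported). Each retained component's sign is fixed
    so that its peak cross-correlation with the log-RMS power is
    positive (falling back to a positive-skew convention when no power
    series is supplied).
    """
    traces = np.stack([r.trace for r in rois], axis=1)  # (t, n)
    sds = traces.std(axis=0, ddof=0)
    dropped = [i for i in range(traces.shape[1]) if sds[i] == 0]
    keep = [i for i in range(traces.shape[1]) if sds[i] > 0]
    if len(keep) < n_pc:
        raise ValueError(
            f"only {len(keep)} usable neurons for {n_pc} components")
    z = (traces[:, keep] - traces[:, keep].mean(axis=0)) / sds[keep]
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(z)              # (t, n_pc)
    loadings = pca.components_.T               # (n_kept, n_pc)
    for j in range(n_pc):
        if power is not None:
            _, r = xcorr_trace(scores[:, j], power.values, max_lag)
            flip = np.nanmax(r) < -np.nanmin(r)
        else:
            s = scores[:, j]
            flip = np.mean((s - s.mean()) ** 3) < 0
        if flip:
            scores[:, j] *= -1
            loadings[:, j] *= -1
    centers = [rois[i].center for i in keep]
    return PCADecomposition(scores=scores, loadings=loadings,
                            explained_variance=pca.explained_variance_ratio_,
                            centers=centers, dropped=dropped)


def select_components(pca: PCADecomposition, power: AlignedPower,
                      max_lag: int = 20,
                      min_peak_r: float = 0.2) -> EpClassification:
    """Pick the Ep and pre-Ep components against the LFP power.

    Ep: the component with the highest zero-lag correlation. Pre-Ep:
    among the remaining components, the one with a positive correlogram
    local peak (r >= ``min_peak_r``) at the negative lag closest to
    zero; flagged undefined if no component qualifies.
    """
    n_pc = pca.scores.shape[1]
    corrs = []
    lags = None
    for j in range(n_pc):
        lags, r = xcorr_trace(pca.scores[:, j], power.values, max_lag)
        corrs.append(r)
    corrs = np.stack(corrs)
    zero = max_lag  # index of lag 0
    ep = int(np.nanargmax(corrs[:, zero]))
    best_pc, best_lag, best_r = None, None, -np.inf
    for j in range(n_pc):
        if j == ep:
            continue
        r = corrs[j]
        for i in range(1, zero):  # strictly negative lags
            if not np.isfinite(r[i]):
                continue
            if r[i] >= min_peak_r and r[i] >= r[i - 1] and r[i] >= r[i + 1]:
                lag = int(lags[i])
                if best_lag is None or lag > best_lag or (
                        lag == best_lag and r[i] > best_r):
                    best_pc, best_lag, best_r = j, lag, float(r[i])
    defined = best_pc is not None
    return EpClassification(
        ep_pc=ep,
        pre_ep_pc=best_pc,
        lags=lags,
        correlograms=corrs,
        ep_zero_lag=float(corrs[ep, zero]),
        pre_ep_peak_lag=best_lag,
        pre_ep_defined=defined,
    )


def event_correlograms(classification: EpClassification,
                       pca: PCADecomposition, power: AlignedPower,
                       event_frames: np.ndarray, frame_rate: float,
                       window: float = 25.0,
                       max_lag: int = 20) -> dict[str, np.ndarray]:
    """Mean per-event correlogram of each selected component vs power.

    For each event frame, the correlogram is computed within a window of
    ``window`` seconds centered on the event, then averaged over events.
    Windows clipped by the recording edge are truncated and flagged.
    """
    events = np.asarray(event_frames, dtype=int)
    if events.size == 0:
        raise ValueError("no events")
    half = int(round(window * frame_rate / 2.0))
    t = power.n_frames
    out: dict[str, np.ndarray] = {"lags": np.arange(-max_lag, max_lag + 1)}
    truncated = False
    classes = {"ep": classification.ep_pc}
    if classification.pre_ep_defined:
        classes["pre_ep"] = classification.pre_ep_pc
    for name, j in classes.items():
        acc = []
        for ev in events:
            lo, hi = ev - half, ev + half + 1
            if lo < 0 or hi > t:
                truncated = True
                lo, hi = max(0, lo), min(t, hi)
            if hi - lo < 2 * max_lag + 2:
                continue
            _, r = xcorr_trace(pca.scores[lo:hi, j], power.values[lo:hi],
                               max_lag)
            acc.append(r)
        if not acc:
            raise ValueError("all event windows too short")
        out[name] = np.nanmean(np.stack(acc), axis=0)
    out["truncated"] = np.array(truncated)
    return out


def _normalized_loadings(loadings: np.ndarray) -> np.ndarray:
    """Loading / max loading over neurons; negative loadings -> NaN."""
    m = loadings.max()
    if m <= 0:
        return np.full_like(loadings, np.nan)
    norm = loadings / m
    norm[loadings < 0] = np.nan
    return norm


def loading_maps(pca: PCADecomposition, classification: EpClassification,
                 shape: tuple[int, int], both_threshold: float = 0.2,
                 n_profile_bins: int = 16,
                 axis: str = "y") -> dict[str, LoadingMap]:
    """Class-exclusive normalized-loading maps for Ep and pre-Ep.

    Each neuron gets its normalized loading (loading divided by the
    component's maximum loading); negative-loading neurons are removed,
    as are neurons exceeding ``both_threshold`` in both classes. The
    rostro-caudal profile sums normalized loadings in bins along the
    declared image axis (y by default).
    """
    classes = {"ep": classification.ep_pc}
    if classification.pre_ep_defined:
        classes["pre_ep"] = classification.pre_ep_pc
    norm = {name: _normalized_loadings(pca.loadings[:, j])
            for name, j in classes.items()}
    if len(norm) == 2:
        both = (np.nan_to_num(norm["ep"]) > both_threshold) & \
               (np.nan_to_num(norm["pre_ep"]) > both_threshold)
    else:
        both = np.zeros(pca.loadings.shape[0], dtype=bool)
    out: dict[str, LoadingMap] = {}
    h, w = shape
    extent = h if axis == "y" else w
    edges = np.linspace(0, extent, n_profile_bins + 1)
    for name, vals in norm.items():
        keep = np.isfinite(vals) & ~both
        ids = np.flatnonzero(keep)
        img = np.zeros(shape)
        pos = np.array([pca.centers[i][1] if axis == "y"
                        else pca.centers[i][0] for i in ids], dtype=float)
        for i in ids:
            x, y = pca.centers[i]
            if 0 <= y < h and 0 <= x < w:
                img[y, x] = max(img[y, x], vals[i])
        profile = np.zeros(n_profile_bins)
        if ids.size:
            which = np.clip(np.digitize(pos, edges) - 1, 0,
                            n_profile_bins - 1)
            np.add.at(profile, which, vals[ids])
        out[name] = LoadingMap(
            values=img,
            neuron_ids=ids,
            normalized_loadings=vals[ids],
            profile_bins=(edges[:-1] + edges[1:]) / 2.0,
            profile=profile,
            empty=ids.size == 0,
        )
    return out


def _mask_moments(mask: np.ndarray) -> tuple[np.ndarray, float, float]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask")
    centroid = np.array([xs.mean(), ys.mean()])
    cov = np.cov(np.stack([xs, ys]).astype(float))
    evals, evecs = np.linalg.eigh(cov)
    angle = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
    scale = float(np.sqrt(ys.size))
    return centroid, angle, scale


def collective_map(maps: list[np.ndarray], masks: list[np.ndarray],
                   reference_mask: np.ndarray,
                   displacement_fields: list[np.ndarray] | None = None
                   ) -> np.ndarray:
    """Voxelwise maximum over registered per-fish maps.

    Each fish map is registered to the reference mask by a similarity
    transform derived from silhouette moments (centroid, principal-axis
    angle, sqrt-area scale). Externally computed displacement fields
    (shape (2, h, w): dy, dx per pixel) may be supplied instead for
    non-rigid registration done elsewhere.
    """
    if not maps:
        raise ValueError("need at least one map")
    ref_c, ref_a, ref_s = _mask_moments(reference_mask)
    out = np.full(reference_mask.shape, -np.inf)
    for i, (m, msk) in enumerate(zip(maps, masks)):
        if m.shape != msk.shape:
            raise ValueError("map/mask grid mismatch")
        if displacement_fields is not None:
            dy, dx = displacement_fields[i]
            yy, xx = np.mgrid[:m.shape[0], :m.shape[1]]
            reg = ndimage.map_coordinates(m, [yy + dy, xx + dx], order=1,
                                          mode="constant", cval=0.0)
        else:
            c, a, s = _mask_moments(msk)
            # map reference coordinates back into fish coordinates
            t_ref = SimilarityTransform(translation=-ref_c)
            t_rs = SimilarityTransform(scale=s / ref_s,
                                       rotation=a - ref_a)
            t_back = SimilarityTransform(translation=c)
            tform = t_ref + t_rs + t_back
            reg = warp(m, tform, output_shape=reference_mask.shape,
                       order=1, mode="constant", cval=0.0,
                       preserve_range=True)
        out = np.maximum(out, reg)
    return out
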