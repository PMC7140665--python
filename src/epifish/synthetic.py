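"""Paired synthetic LFP + calcium recordings with full ground truth.

Every detection stage of the pipeline can be scored against recordings
generated here: high-frequency bursts planted in the LFP with a known
log-power excess, contiguous Ca2+ domains placed inside atlas regions,
and two neuron cohorts (one coincident with the bursts, one leading by a
configurable interval). All randomness flows from one seed.

Conventions: movies are generated on the *native* pixel grid; domain
ground truth is bookkept on the analysis grid (after the declared
``bin_factor``). SNR is the peak transient dF/F0 divided by the
per-pixel noise SD at native resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from epifish.calcium_dff import FluorescenceStack
from epifish.io_formats import RecordingBundle, RegionAtlas
from epifish.lfp_power import LFPTrace, bandpass

__all__ = [
    "GroundTruth",
    "default_atlas",
    "gcamp_kernel",
    "gen_lfp",
    "gen_movie",
    "gen_condition_suite",
    "CONDITIONS",
]

CONDITIONS = ("WT", "PTZ", "MO", "MO+VPA")


@dataclass
class GroundTruth:
    """Retrievable record of every planted structure."""

    seed: int
    burst_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    burst_duration: float = 0.0
    burst_delta: float = 0.0
    artifact_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    domains: list[dict] = field(default_factory=list)
    neurons: list[dict] = field(default_factory=list)
    movement_frames: np.ndarray = field(default_factory=lambda:
                                        np.empty(0, dtype=int))
    bin_factor: int = 1
    frame_rate: float = 4.0
    dt_pre: float = 0.0
    condition: str | None = None
    flags: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v
        payload = {k: enc(v) for k, v in self.__dict__.items()}
        payload["domains"] = [
            {k: enc(v) for k, v in d.items()} for d in self.domains]
        payload["neurons"] = [
            {k: enc(v) for k, v in d.items()} for d in self.neurons]
        Path(path).write_text(json.dumps(payload, indent=1))


def default_atlas(shape: tuple[int, int]) -> RegionAtlas:
    """Toy larval-brain atlas: elliptical brain, OT / Cb / MOb bands.

    The optic tectum occupies the anterior (low-y) part of the ellipse,
    the cerebellum a central band, the medulla the posterior part.
    """
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    inside = ((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.38 * w)) ** 2 <= 1
    labels = np.zeros(shape, dtype=np.int32)
    ys = np.nonzero(inside.any(axis=1))[0]
    y0, y1 = ys[0], ys[-1]
    b1 = y0 + int(0.40 * (y1 - y0))
    b2 = y0 + int(0.65 * (y1 - y0))
    labels[inside & (yy <= b1)] = 1                 # OT
    labels[inside & (yy > b1) & (yy <= b2)] = 2     # Cb
    labels[inside & (yy > b2)] = 3                  # MOb
    return RegionAtlas(labels=labels)


def _pink_noise(n: int, rng: np.random.Generator,
                exponent: float = 0.5) -> np.ndarray:
    """1/f^exponent amplitude-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent)
    shaping[0] = 0.0
    shaping /= np.sqrt(np.mean(shaping[1:] ** 2))
    out = np.fft.irfft(spec * shaping, n)
    return out / out.std()


def _sample_times(rng: np.random.Generator, n: int, lo: float, hi: float,
                  min_gap: float, max_tries: int = 10_000
                  ) -> tuple[np.ndarray, bool]:
    """Rejection-sample ``n`` times in [lo, hi] separated by min_gap."""
    times: list[float] = []
    tries = 0
    while len(times) < n and tries < max_tries:
        t = float(rng.uniform(lo, hi))
        tries += 1
        if all(abs(t - u) >= min_gap for u in times):
            times.append(t)
    return np.sort(np.asarray(times)), len(times) == n


def gen_lfp(duration: float, rate: float = 5000.0, n_bursts: int = 10,
            burst_delta: float = 1.0, burst_duration: float = 2.0,
            n_artifacts: int = 0, artifact_amplitude: float = 6.0,
            noise_rms: float = 20.0, band: tuple[float, float] = (30.0, 95.0),
            seed: int = 0) -> tuple[LFPTrace, GroundTruth]:
    """Synthetic LFP: 1/f background + band-limited burst packets.

    Bursts are 30-95 Hz noise packets whose in-band RMS raises the total
    windowed log10 power by ``burst_delta`` above background. Optional
    artifacts are smooth low-frequency transients with no in-band power
    (the wild-type-like confound).
    """
    if duration < 10:
        raise ValueError("duration must be >= 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    bg = _pink_noise(n, rng) * noise_rms
    trace = bg.copy()
    gt = GroundTruth(seed=seed, burst_duration=burst_duration,
                     burst_delta=burst_delta)

    # background in-band RMS sets the packet scale
    bg_band = bandpass(LFPTrace(bg, rate), band).samples
    bg_band_rms = float(np.sqrt(np.mean(bg_band ** 2)))

    margin = 1.0
    if n_bursts > 0:
        times, ok = _sample_times(
            rng, n_bursts, margin, duration - burst_duration - margin,
            min_gap=burst_duration + 2.0)
        if not ok:
            gt.flags.append("burst_sampling_truncated")
        gt.burst_times = times
        blen = int(round(burst_duration * rate))
        ramp = max(1, int(0.01 * rate))
        env = np.ones(blen)
        env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[-ramp:] = env[:ramp][::-1]
        target = bg_band_rms * np.sqrt(10.0 ** (2 * burst_delta) - 1.0)
        sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
        for t in times:
            packet = sps.sosfiltfilt(sos, rng.standard_normal(blen))
            packet *= env
            packet *= target / np.sqrt(np.mean(packet ** 2))
            i0 = int(round(t * rate))
            trace[i0:i0 + blen] += packet

    if n_artifacts > 0:
        lo, hi = 2.0, duration - 2.0
        occupied = list(gt.burst_times)
        arts: list[float] = []
        tries = 0
        while len(arts) < n_artifacts and tries < 10_000:
            t = float(rng.uniform(lo, hi))
            tries += 1
            if all(abs(t - u) >= 3.0 for u in occupied + arts):
                arts.append(t)
        gt.artifact_times = np.sort(np.asarray(arts))
        sigma = 0.3
        tt = np.arange(n) / rate
        for t in gt.artifact_times:
            i0 = max(0, int((t - 4 * sigma) * rate))
            i1 = min(n, int((t + 4 * sigma) * rate))
            bump = artifact_amplitude * noise_rms * np.exp(
                -0.5 * ((tt[i0:i1] - t) / sigma) ** 2)
            trace[i0:i1] += bump

    return LFPTrace(samples=trace, sampling_rate=rate), gt


def gcamp_kernel(frame_rate: float, tau: float = 1.5,
                 n_tau: float = 5.0) -> np.ndarray:
    """Instant-rise, exponential-decay indicator kernel, peak 1."""
    n = max(2, int(round(n_tau * tau * frame_rate)))
    return np.exp(-np.arange(n) / (tau * frame_rate))


def _donut_profile(size: int) -> np.ndarray:
    """Cell-body intensity profile: bright ring, dimmer lumen."""
    canvas = size + 1 if size % 2 == 0 else size
    c = canvas // 2
    yy, xx = np.mgrid[:canvas, :canvas]
    r = np.hypot(yy - c, xx - c)
    r_out, r_in = size / 2.0, 0.4 * size / 2.0
    prof = np.zeros((canvas, canvas))
    prof[(r > r_in) & (r <= r_out)] = 1.0
    prof[r <= r_in] = 0.3
    return prof


def _grow_blob(rng: np.random.Generator, mask: np.ndarray,
               n_pixels: int) -> np.ndarray | None:
    """Grow a contiguous pixel blob of ``n_pixels`` inside ``mask``.

    Random accretion from a seed pixel; returns (n, 2) (y, x) or None if
    the region cannot host the blob.
    """
    ys, xs = np.nonzero(mask)
    if ys.size < n_pixels:
        return None
    for _ in range(20):
        k = rng.integers(ys.size)
        blob = {(int(ys[k]), int(xs[k]))}
        frontier = list(blob)
        while len(blob) < n_pixels and frontier:
            y, x = frontier[rng.integers(len(frontier))]
            nbrs = [(y + dy, x + dx)
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
                    if (y + dy, x + dx) not in blob
                    and 0 <= y + dy < mask.shape[0]
                    and 0 <= x + dx < mask.shape[1]
                    and mask[y + dy, x + dx]]
            if not nbrs:
                frontier.remove((y, x))
                continue
            new = nbrs[rng.integers(len(nbrs))]
            blob.add(new)
            frontier.append(new)
        if len(blob) == n_pixels:
            return np.array(sorted(blob))
    return None


def _base_image(shape: tuple[int, int], baseline: float,
                outside_level: float = 5.0,
                edge_softness: float = 4.0) -> np.ndarray:
    """Bright elliptical brain on a dim background, soft edge."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    d = np.sqrt(((yy - cy) / (0.45 * h)) ** 2 +
                ((xx - cx) / (0.38 * w)) ** 2)
    soft = 1.0 / (1.0 + np.exp((d - 1.0) * 0.45 * h / edge_softness))
    return outside_level + (baseline - outside_level) * soft


def gen_movie(dims: tuple[int, int] = (128, 128), frames: int = 240,
              frame_rate: float = 4.0,
              lfp_gt: GroundTruth | None = None,
              neuron_spec: dict | None = None,
              domain_spec: list[dict] | None = None,
              dt_pre: float = 0.0, snr: float = 5.0,
              baseline: float = 100.0, bin_factor: int = 2,
              tau: float = 1.5, amplitude: float = 1.0,
              movement_frames: np.ndarray | None = None,
              seed: int = 0
              ) -> tuple[FluorescenceStack, GroundTruth, RegionAtlas]:
    """Synthetic time-lapse movie with planted neurons and domains.

    ``neuron_spec``: ``{"n_ep": .., "n_pre": .., "n_silent": ..,
    "cell_size": 10, "anterior_pre": False}``. Ep neurons fire at each
    LFP burst, pre-Ep neurons lead by ``dt_pre`` seconds. ``domain_spec``
    is a list of ``{"region": "Cb", "area": 40, "duration": 10,
    "t0": frame or None, "shape": "plateau"|"gcamp", "lateral": bool}``;
    areas/coordinates are on the analysis (binned) grid and each entry
    is recorded in the ground truth with its voxel volume.

    Returns the stack (native grid), the ground truth, and the atlas on
    the analysis grid.
    """
    h, w = dims
    if h < 64 or w < 64:
        raise ValueError("dims must be >= 64x64")
    if frames < 200:
        raise ValueError("need >= 200 frames")
    rng = np.random.default_rng(seed)
    gt = GroundTruth(seed=seed, bin_factor=bin_factor, frame_rate=frame_rate,
                     dt_pre=dt_pre)
    if lfp_gt is not None:
        gt.burst_times = lfp_gt.burst_times
        gt.burst_duration = lfp_gt.burst_duration
        gt.burst_delta = lfp_gt.burst_delta
        gt.artifact_times = lfp_gt.artifact_times

    burst_frames = np.asarray(
        [int(round(t * frame_rate)) for t in gt.burst_times], dtype=int)
    burst_frames = burst_frames[(burst_frames >= 0) & (burst_frames < frames)]
    lead = int(round(dt_pre * frame_rate))
    if lead and gt.burst_times.size > 1:
        gaps = np.diff(gt.burst_times)
        if dt_pre >= gaps.min():
            raise ValueError("dt_pre exceeds the shortest inter-burst gap")

    atlas = default_atlas((h // bin_factor, w // bin_factor))
    base = _base_image((h, w), baseline)
    signal = np.zeros((frames, h, w))
    kernel = gcamp_kernel(frame_rate, tau=tau)

    # --- neurons -------------------------------------------------------
    if neuron_spec:
        cell_size = int(neuron_spec.get("cell_size", 10))
        prof = _donut_profile(cell_size)
        half = prof.shape[0] // 2
        counts = [("ep", neuron_spec.get("n_ep", 0)),
                  ("pre_ep", neuron_spec.get("n_pre", 0)),
                  ("silent", neuron_spec.get("n_silent", 0))]
        anterior_pre = bool(neuron_spec.get("anterior_pre", False))
        margin = half + 4
        placed: list[tuple[int, int]] = []
        for cls, n_cells in counts:
            for _ in range(n_cells):
                for _try in range(500):
                    if anterior_pre and cls == "pre_ep":
                        y = int(rng.uniform(margin, 0.45 * h))
                    elif anterior_pre and cls == "ep":
                        y = int(rng.uniform(0.55 * h, h - margin))
                    else:
                        y = int(rng.uniform(margin, h - margin))
                    x = int(rng.uniform(margin, w - margin))
                    if all((x - px) ** 2 + (y - py) ** 2
                           >= (2.2 * half) ** 2 for px, py in placed):
                        break
                else:
                    continue
                placed.append((x, y))
                # brighten the soma in the baseline image
                sl = (slice(y - half, y + half + 1),
                      slice(x - half, x + half + 1))
                base[sl] += 0.6 * baseline * prof
                amp = amplitude * float(rng.uniform(0.8, 1.2))
                impulses = np.zeros(frames)
                if cls == "ep":
                    evs = burst_frames
                elif cls == "pre_ep":
                    evs = burst_frames - lead
                else:
                    evs = np.empty(0, dtype=int)
                for f in evs:
                    if 0 <= f < frames:
                        impulses[f] = amp * float(rng.uniform(0.8, 1.2))
                tr = np.convolve(impulses, kernel)[:frames]
                if tr.any():
                    soma = prof > 0
                    signal[:, sl[0], sl[1]][:, soma] += tr[:, None]
                gt.neurons.append({
                    "center": (x, y), "cls": cls,
                    "lead_s": dt_pre if cls == "pre_ep" else 0.0,
                    "amplitude": amp, "cell_size": cell_size})

    # --- domains -------------------------------------------------------
    if domain_spec:
        region_ids = {v: k for k, v in atlas.names.items()}
        bh, bw = atlas.labels.shape
        for spec in domain_spec:
            region = spec.get("region", "Cb")
            mask = atlas.labels == region_ids.get(region, 0)
            if region == "brain":
                mask = atlas.labels > 0
            if spec.get("lateral", False):
                xxb = np.arange(bw)[None, :]
                mask = mask & (np.abs(xxb - bw / 2.0) > 0.12 * bw)
            area = int(spec["area"])
            dur = int(spec["duration"])
            blob = _grow_blob(rng, mask, area)
            if blob is None:
                gt.flags.append(f"domain_placement_failed_{region}")
                continue
            t0 = spec.get("t0")
            if t0 is None:
                if burst_frames.size:
                    t0 = int(burst_frames[rng.integers(burst_frames.size)])
                else:
                    t0 = int(rng.integers(5, frames - dur - 5))
            t0 = int(np.clip(t0, 0, frames - dur))
            amp = float(spec.get("amplitude", amplitude))
            shape = spec.get("shape", "plateau")
            if shape == "gcamp":
                tr = np.convolve(
                    np.eye(1, frames, t0).ravel() * amp, kernel)[:frames]
                active = tr > 0.05 * amp
            else:
                tr = np.zeros(frames)
                tr[t0:t0 + dur] = amp
                active = tr > 0
            ys = blob[:, 0]
            xs = blob[:, 1]
            for rep_y in range(bin_factor):
                for rep_x in range(bin_factor):
                    signal[:, ys * bin_factor + rep_y,
                           xs * bin_factor + rep_x] += tr[:, None]
            gt.domains.append({
                "pixels": blob, "t0": t0,
                "duration": int(active.sum()) if shape == "gcamp" else dur,
                "volume": area * (int(active.sum()) if shape == "gcamp"
                                  else dur),
                "amplitude": amp, "region": region, "shape": shape})

    counts3 = base[None] * (1.0 + signal)

    if movement_frames is not None and len(movement_frames):
        gt.movement_frames = np.asarray(movement_frames, dtype=int)
        for f in gt.movement_frames:
            if 0 <= f < frames:
                counts3[f] = np.roll(counts3[f], shift=(1, 1), axis=(0, 1))

    sigma0 = amplitude * baseline / snr
    noise_sd = sigma0 * np.sqrt(np.maximum(counts3, 0) / baseline)
    movie = counts3 + rng.standard_normal(counts3.shape) * noise_sd
    movie = np.maximum(movie, 0.0)
    stack = FluorescenceStack(pixels=movie, frame_rate=frame_rate,
                              pixel_size=1.2)
    return stack, gt, atlas


# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------

def gen_condition_suite(condition: str, seed: int = 0,
                        duration: float = 90.0,
                        dims: tuple[int, int] = (128, 128)
                        ) -> tuple[RecordingBundle, GroundTruth]:
    """Preset paired recording for one experimental condition.

    WT: low-frequency artifacts plus tiny sparse domains; PTZ: frequent
    small lateral-cerebellum domains (300-700 voxels) and one
    near-global event; MO: patchy midbrain/hindbrain domains of
    intermediate size; MO+VPA: the MO preset with burst amplitude and
    rate strongly reduced and only sub-threshold domains.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"choose from {CONDITIONS}")
    rng = np.random.default_rng(seed)
    frame_rate = 4.0
    frames = int(duration * frame_rate)
    kw: dict = {}
    movement: np.ndarray | None = None

    if condition == "WT":
        lfp, lgt = gen_lfp(duration, n_bursts=0, n_artifacts=5,
                           seed=seed)
        movement = _movement_from_times(lgt.artifact_times, frame_rate,
                                        frames)
        domains = [{"region": "OT", "area": 12, "duration": 4,
                    "t0": int(f)} for f in movement[::2]]
        kw = dict(domain_spec=domains, snr=4.0)
    elif condition == "PTZ":
        lfp, lgt = gen_lfp(duration, n_bursts=9, burst_delta=1.2,
                           seed=seed)
        bf = np.round(lgt.burst_times * frame_rate).astype(int)
        domains = [{"region": "Cb", "lateral": True,
                    "area": int(rng.integers(34, 64)),
                    "duration": int(rng.integers(9, 12)),
                    "t0": int(f)} for f in bf[:-1]]
        domains.append({"region": "brain", "area": 700, "duration": 12,
                        "t0": int(bf[-1])})
        kw = dict(domain_spec=domains, snr=4.0)
    elif condition == "MO":
        lfp, lgt = gen_lfp(duration, n_bursts=7, burst_delta=1.0,
                           seed=seed)
        bf = np.round(lgt.burst_times * frame_rate).astype(int)
        regions = ["OT", "Cb"]
        domains = [{"region": regions[i % 2],
                    "area": int(rng.integers(34, 50)),
                    "duration": int(rng.integers(9, 11)),
                    "t0": int(f)} for i, f in enumerate(bf)]
        kw = dict(domain_spec=domains, snr=4.0)
    else:  # MO+VPA
        lfp, lgt = gen_lfp(duration, n_bursts=3, burst_delta=0.45,
                           seed=seed)
        bf = np.round(lgt.burst_times * frame_rate).astype(int)
        movement = _movement_from_times(lgt.burst_times, frame_rate, frames)
        domains = [{"region": "Cb", "area": 18, "duration": 6,
                    "t0": int(f), "amplitude": 0.5} for f in bf]
        kw = dict(domain_spec=domains, snr=4.0, amplitude=1.0)

    stack, gt, atlas = gen_movie(dims=dims, frames=frames,
                                 frame_rate=frame_rate, lfp_gt=lgt,
                                 movement_frames=movement,
                                 seed=seed + 1, **kw)
    gt.condition = condition
    bundle = RecordingBundle(
        lfp=lfp, stack=stack, frame_times=stack.frame_times(),
        atlas=atlas, metadata={"condition": condition, "seed": seed})
    return bundle, gt


def _movement_from_times(times: np.ndarray, frame_rate: float,
                         frames: int) -> np.ndarray:
    """Two consecutive shifted frames per event time."""
    out: list[int] = []
    for t in times:
        f = int(round(t * frame_rate))
        for g in (f, f + 1):
            if 0 <= g < frames:
                out.append(g)
    return np.unique(np.asarray(out, dtype=int))
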