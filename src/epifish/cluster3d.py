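"""Spatiotemporal Ca2+ domains: connected components in (x, y, t).

Supra-threshold voxels are grouped into maximal topologically connected
components on the 3-D binary stack, measured (volume, duration, maximum
per-frame surface, origin) and classified by anatomical region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from epifish.calcium_dff import BinaryStack
from epifish.io_formats import RegionAtlas

__all__ = [
    "CaCluster",
    "find_clusters",
    "cluster_metrics",
    "classify_by_region",
    "region_activity",
    "cluster_table",
]


@dataclass(frozen=True)
class CaCluster:
    """A connected spatiotemporal activity domain.

    ``voxels`` is an (n, 3) int array of (t, y, x) indices. ``origin`` is
    the centroid (x, y) of the cluster's earliest-frame pixels, rounded
    to the nearest pixel for atlas lookup.
    """

    id: int
    voxels: np.ndarray

    @property
    def volume(self) -> int:
        return self.voxels.shape[0]

    @property
    def t_min(self) -> int:
        return int(self.voxels[:, 0].min())

    @property
    def t_max(self) -> int:
        return int(self.voxels[:, 0].max())

    @property
    def duration(self) -> int:
        """Duration in frames: t_max - t_min + 1."""
        return self.t_max - self.t_min + 1

    @property
    def max_surface(self) -> int:
        """Maximum per-frame pixel count."""
        counts = np.bincount(self.voxels[:, 0] - self.t_min)
        return int(counts.max())

    @property
    def origin(self) -> tuple[int, int]:
        """(x, y) centroid of the first-frame pixels, rounded."""
        first = self.voxels[self.voxels[:, 0] == self.t_min]
        y = int(np.rint(first[:, 1].mean()))
        x = int(np.rint(first[:, 2].mean()))
        return x, y


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def find_clusters(binary: BinaryStack | np.ndarray,
                  connectivity: int = 26) -> list[CaCluster]:
    """Partition positive voxels into maximal connected components.

    Ids are deterministic: clusters are sorted by the lexicographic
    (t, y, x) of their first voxel.
    """
    vox = binary.voxels if isinstance(binary, BinaryStack) else binary
    vox = np.asarray(vox, dtype=bool)
    labels, n = ndimage.label(vox, structure=_structure(connectivity))
    if n == 0:
        return []
    coords = np.argwhere(vox)  # sorted lexicographically by (t, y, x)
    lab = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    order = np.argsort(lab, kind="stable")
    coords, lab = coords[order], lab[order]
    bounds = np.searchsorted(lab, np.arange(1, n + 2))
    groups = [coords[bounds[i]:bounds[i + 1]] for i in range(n)]
    # deterministic ids: by first (lexicographically smallest) voxel
    groups.sort(key=lambda g: tuple(g[0]))
    return [CaCluster(id=i, voxels=g) for i, g in enumerate(groups)]


def cluster_metrics(cluster: CaCluster, pixel_size: float | None = None,
                    frame_rate: float | None = None) -> dict:
    """Scalar metrics of one cluster.

    With ``pixel_size`` (um) and/or ``frame_rate`` (Hz) given, physical
    units are added alongside the voxel/frame counts.
    """
    if cluster.volume == 0:
        raise ValueError("empty cluster")
    x, y = cluster.origin
    out = {
        "volume": cluster.volume,
        "duration": cluster.duration,
        "max_surface": cluster.max_surface,
        "origin_x": x,
        "origin_y": y,
        "t_min": cluster.t_min,
    }
    if pixel_size is not None:
        out["max_surface_um2"] = cluster.max_surface * pixel_size ** 2
    if frame_rate is not None:
        out["duration_s"] = cluster.duration / frame_rate
    return out


def classify_by_region(clusters: Iterable[CaCluster], atlas: RegionAtlas,
                       min_volume: int = 300) -> pd.DataFrame:
    """Count large clusters per region of origin, normalized.

    Only clusters with volume strictly greater than ``min_volume`` are
    counted. The origin pixel is looked up in the atlas; origins outside
    any region are tallied under ``outside``. Counts are normalized to
    the total number of counted domains (sum to 1 when any qualify).
    """
    counts: dict[str, int] = {name: 0 for name in atlas.names.values()}
    counts["outside"] = 0
    total = 0
    for c in clusters:
        if c.volume <= min_volume:
            continue
        x, y = c.origin
        h, w = atlas.labels.shape
        if 0 <= y < h and 0 <= x < w:
            label = int(atlas.labels[y, x])
        else:
            label = 0
        counts[atlas.names.get(label, "outside")] += 1
        total += 1
    rows = [{"region": k, "count": v,
             "fraction": v / total if total else 0.0}
            for k, v in counts.items()]
    return pd.DataFrame(rows)


def region_activity(binary: BinaryStack | np.ndarray,
                    atlas: RegionAtlas) -> dict[str, int]:
    """Total positive voxel count per atlas region."""
    vox = binary.voxels if isinstance(binary, BinaryStack) else binary
    vox = np.asarray(vox, dtype=bool)
    if vox.shape[1:] != atlas.labels.shape:
        raise ValueError("binary stack and atlas grids differ")
    per_pixel = vox.sum(axis=0)
    out: dict[str, int] = {}
    for label, name in atlas.names.items():
        out[name] = int(per_pixel[atlas.labels == label].sum())
    out["outside"] = int(per_pixel[atlas.labels == 0].sum())
    return out


def cluster_table(clusters: Iterable[CaCluster],
                  atlas: RegionAtlas | None = None,
                  pixel_size: float | None = None,
                  frame_rate: float | None = None) -> pd.DataFrame:
    """Tabulate clusters (one row each) for export."""
    rows = []
    for c in clusters:
        row = {"id": c.id, **cluster_metrics(c, pixel_size, frame_rate)}
        if atlas is not None:
            x, y = c.origin
            h, w = atlas.labels.shape
            label = int(atlas.labels[y, x]) if (0 <= y < h and 0 <= x < w) else 0
            row["region"] = atlas.names.get(label, "outside")
        rows.append(row)
    return pd.DataFrame(rows)
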