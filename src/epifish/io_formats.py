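"""Readers/writers for external data and results.

Single source of truth for grids, units, and time bases. LFP traces are
delimited text (one value per line) or declared raw binary; imaging
stacks and maps are multi-page TIFF; tables are tab-separated text;
cluster voxel lists and PCA arrays go into an HDF5 container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Any

import h5py
import numpy as np
import pandas as pd
import tifffile

from epifish.lfp_power import LFPTrace

if TYPE_CHECKING:  # pragma: no cover
    from epifish.calcium_dff import FluorescenceStack
    from epifish.cluster3d import CaCluster

__all__ = [
    "RegionAtlas",
    "RecordingBundle",
    "read_lfp",
    "read_stack",
    "read_atlas",
    "write_map",
    "read_map",
    "write_table",
    "read_table",
    "write_clusters",
    "read_clusters",
    "write_arrays",
    "read_arrays",
]

REGION_NAMES = {1: "OT", 2: "Cb", 3: "MOb"}


@dataclass(frozen=True)
class RegionAtlas:
    """Anatomical label image on the analysis grid.

    ``labels`` is an integer (y, x) image; ``names`` maps each nonzero
    label to a region name (OT, Cb, MOb at minimum). Label 0 is outside
    the brain.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=lambda: dict(REGION_NAMES))

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        object.__setattr__(self, "labels", lab)
        present = set(np.unique(lab)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValueError(f"atlas labels without a name: {sorted(unnamed)}")


@dataclass
class RecordingBundle:
    """One paired recording: LFP + imaging + optional atlas."""

    lfp: LFPTrace
    stack: "FluorescenceStack"
    frame_times: np.ndarray
    atlas: RegionAtlas | None = None
    metadata: dict[str, Any] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ft = np.asarray(self.frame_times, dtype=float)
        self.frame_times = ft
        if ft.size != self.stack.n_frames:
            raise ValueError("frame_times length != stack frame count")
        if np.any(np.diff(ft) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if ft[0] < 0 or ft[-1] > self.lfp.duration:
            self.flags.append("frame_times_outside_lfp_span")


def read_lfp(path: str | Path, sampling_rate: float,
             dtype: str | None = None) -> LFPTrace:
    """Read an LFP trace in microvolts.

    Text files hold one value per line (an optional non-numeric header
    line is skipped). Raw binary requires an explicit little-endian
    ``dtype`` (e.g. ``"<f4"``, ``"<i2"``). Non-finite rows are rejected
    with a warning carrying the count.
    """
    path = Path(path)
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if not path.exists():
        raise FileNotFoundError(path)
    if dtype is not None:
        if not str(dtype).startswith("<"):
            raise ValueError("binary dtype must be declared little-endian")
        values = np.fromfile(path, dtype=np.dtype(dtype)).astype(float)
    else:
        values = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    values.append(float(line))
                except ValueError:
                    if i == 0:
                        continue  # header line
                    raise ValueError(f"unparseable line {i + 1} in {path}")
        values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n_bad = int((~finite).sum())
    if n_bad:
        warnings.warn(f"{path.name}: dropped {n_bad} non-finite sample(s)",
                      stacklevel=2)
        values = values[finite]
    if values.size == 0:
        raise ValueError(f"empty LFP trace: {path}")
    return LFPTrace(samples=values, sampling_rate=sampling_rate)


def read_stack(path: str | Path, frame_rate: float = 1.0,
               pixel_size: float = 1.0) -> "FluorescenceStack":
    """Read a multi-page TIFF time-lapse stack.

    Frame rate and pixel size come from the caller/config; TIFF metadata
    is not trusted. Pages must share one shape.
    """
    from epifish.calcium_dff import FluorescenceStack

    with tifffile.TiffFile(str(path)) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"ragged TIFF pages: {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.shape[0] == 0:
        raise ValueError("expected a non-empty (t, y, x) stack")
    return FluorescenceStack(pixels=data.astype(float), frame_rate=frame_rate,
                             pixel_size=pixel_size)


def read_atlas(path: str | Path,
               names: dict[int, str] | None = None) -> RegionAtlas:
    """Read a label-image TIFF as a region atlas."""
    labels = tifffile.imread(str(path))
    if labels.ndim != 2:
        raise ValueError("atlas must be a single 2-D label image")
    return RegionAtlas(labels=labels.astype(np.int32),
                       names=dict(names or REGION_NAMES))


def write_map(array: np.ndarray, path: str | Path) -> None:
    """Write a 2-D/3-D float map as TIFF, preserving dtype."""
    tifffile.imwrite(str(path), np.asarray(array))


def read_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as tab-separated text."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clusters(clusters: list["CaCluster"], path: str | Path) -> None:
    """Store cluster voxel lists in an HDF5 container (bit-exact)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["n_clusters"] = len(clusters)
        for c in clusters:
            fh.create_dataset(f"cluster_{c.id:06d}",
                              data=c.voxels.astype(np.int64))


def read_clusters(path: str | Path) -> list["CaCluster"]:
    from epifish.cluster3d import CaCluster

    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh.keys()):
            cid = int(name.split("_")[1])
            out.append(CaCluster(id=cid, voxels=fh[name][()]))
    return out


def write_arrays(arrays: dict[str, np.ndarray], path: str | Path) -> None:
    """Store named numeric arrays (PCA scores/loadings etc.) in HDF5."""
    with h5py.File(path, "w") as fh:
        for key, arr in arrays.items():
            fh.create_dataset(key, data=np.asarray(arr))


def read_arrays(path: str | Path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as fh:
        return {key: fh[key][()] for key in fh.keys()}
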