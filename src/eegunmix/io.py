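"""Plain-text (and HDF5) readers/writers for every on-disk artifact.

All on-disk voxel and region indices are 1-based (the in-memory convention
is 0-based); every tabular format is whitespace/tab-delimited text with
``#`` comments.  Matrices can also round-trip through an HDF5 container
with a single dataset (row = electrode) when the filename ends in ``.h5``
and h5py is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import ICohResult
from .headmodel import ElectrodeMontage, SourceSpace
from .simulate import TimeSeriesSet
from .unmix import Parcellation

__all__ = [
    "read_montage",
    "write_montage",
    "read_source_space",
    "write_source_space",
    "read_matrix",
    "write_matrix",
    "read_parcellation",
    "write_parcellation",
    "read_directions",
    "read_timeseries",
    "write_timeseries",
    "write_connectivity_table",
]


def read_montage(path) -> ElectrodeMontage:
    """Whitespace-delimited rows: label x y z."""
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return ElectrodeMontage(tuple(labels), np.asarray(rows))


def write_montage(path, montage: ElectrodeMontage):
    with open(path, "w") as fh:
        fh.write("# label x y z\n")
        for lab, p in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {p[0]:+.12f} {p[1]:+.12f} {p[2]:+.12f}\n")


def read_source_space(path) -> SourceSpace:
    """Delimited rows: px py pz [nx ny nz]."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] not in (3, 6):
        raise ValueError("source space rows must have 3 or 6 columns")
    normals = arr[:, 3:6] if arr.shape[1] == 6 else None
    return SourceSpace(arr[:, :3], normals)


def write_source_space(path, src: SourceSpace):
    arr = (
        src.positions
        if src.normals is None
        else np.hstack([src.positions, src.normals])
    )
    np.savetxt(path, arr, fmt="%+.12e", header="px py pz" + (" nx ny nz" if src.normals is not None else ""))


def read_matrix(path, dataset: str = "matrix") -> np.ndarray:
    """Delimited text matrix, or one dataset of an HDF5 container (*.h5)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            return np.asarray(fh[dataset])
    return np.loadtxt(path, ndmin=2)


def write_matrix(path, M: np.ndarray, dataset: str = "matrix"):
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset(dataset, data=np.asarray(M, float))
        return
    np.savetxt(path, np.asarray(M, float), fmt="%+.12e")


def read_parcellation(path, n_voxels: int | None = None) -> Parcellation:
    """Delimited rows "voxel_index region_id", both 1-based on disk."""
    arr = np.loadtxt(path, dtype=int, ndmin=2)
    vox, reg = arr[:, 0] - 1, arr[:, 1] - 1
    if np.any(vox < 0) or np.any(reg < 0):
        raise ValueError("on-disk voxel/region indices are 1-based")
    regions = tuple(vox[reg == i] for i in np.unique(reg))
    return Parcellation(regions, n_voxels=n_voxels)


def write_parcellation(path, parc: Parcellation):
    with open(path, "w") as fh:
        fh.write("# voxel_index region_id (1-based)\n")
        for l, r in enumerate(parc.regions):
            for u in r:
                fh.write(f"{u + 1} {l + 1}\n")


def read_directions(path) -> np.ndarray:
    """Per-voxel unit 3-vectors, same layout as source-space normals."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 3:
        raise ValueError("direction rows must have 3 columns")
    return arr


def read_timeseries(path) -> TimeSeriesSet:
    """Tab-delimited table, one column per channel, header row = labels."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return TimeSeriesSet(df.to_numpy().T, tuple(df.columns))


def write_timeseries(path, ts: TimeSeriesSet):
    labels = ts.labels or tuple(f"ch{i + 1}" for i in range(ts.n_channels))
    pd.DataFrame(ts.values.T, columns=list(labels)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_connectivity_table(path, result: ICohResult):
    """Long-format table: from, to, frequency, icoh."""
    labels = result.labels or tuple(
        str(i + 1) for i in range(result.n_nodes)
    )
    rows = []
    for i in range(result.n_nodes):
        for j in range(result.n_nodes):
            if i == j:
                continue
            for k, f in enumerate(result.frequencies):
                rows.append((labels[j], labels[i], f, result.values[i, j, k]))
    pd.DataFrame(rows, columns=["from", "to", "frequency", "icoh"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
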