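"""Matrix readers/writers (TSV with header row, HDF5 datasets)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "read_hdf5", "write_hdf5"]


def read_matrix(path, format: str | None = None, dataset: str = "X"):
    """Read a numeric matrix; returns (values, column labels).

    TSV files must have a header row and rectangular numeric body; HDF5
    files must contain the named dataset.  The format is inferred from the
    suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "tsv"
    if format == "hdf5":
        values = read_hdf5(path, dataset)
        return values, [f"c{i}" for i in range(values.shape[1])]
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed TSV {path}: {exc}") from exc
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = df.columns[df.dtypes == object].tolist()
        raise ValueError(
            f"non-numeric cells in {path} (columns {bad}): {exc}"
        ) from exc
    return values, list(df.columns)


def write_matrix(path, values: np.ndarray, labels=None) -> None:
    values = np.atleast_2d(np.asarray(values))
    if labels is None:
        labels = [f"c{i}" for i in range(values.shape[1])]
    pd.DataFrame(values, columns=labels).to_csv(path, sep="\t", index=False)


def read_hdf5(path, dataset: str) -> np.ndarray:
    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise KeyError(
                f"dataset /{dataset} not found in {path}; has {sorted(f.keys())}"
            )
        return f[dataset][()]


def write_hdf5(path, arrays: dict, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
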