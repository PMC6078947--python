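"""Dataset persistence: HDF5 epoch container + TSV behavioral table.

A dataset directory holds ``epochs.h5`` (datasets ``data``, ``times``,
``channel_names`` and a ``metadata/`` group with one dataset per column,
plus ``sfreq`` and column-order attributes) and ``behavior.tsv`` with the
documented columns ``subject, item, round, correct, rt_s, recalled_s3``.
Round-trips are lossless: array values are bit-identical and metadata
dtypes are preserved.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._exceptions import DataFormatError
from .containers import EpochSet

__all__ = ["BEHAVIOR_COLUMNS", "write_dataset", "read_dataset", "write_epochs", "read_epochs"]

BEHAVIOR_COLUMNS = ["subject", "item", "round", "correct", "rt_s", "recalled_s3"]


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` to one HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset(
            "channel_names", data=np.array(epochs.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["sfreq"] = float(epochs.sfreq)
        grp = f.create_group("metadata")
        grp.attrs["columns"] = list(epochs.metadata.columns)
        for col in epochs.metadata.columns:
            values = epochs.metadata[col].to_numpy()
            if values.dtype == object or values.dtype.kind == "U":
                grp.create_dataset(
                    col, data=[str(v) for v in values], dtype=h5py.string_dtype()
                )
            else:
                grp.create_dataset(col, data=values)
    return path


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("data", "times", "channel_names"):
            if name not in f:
                raise DataFormatError(f"epoch file {path} is missing dataset '{name}'")
        if "metadata" not in f:
            raise DataFormatError(f"epoch file {path} is missing the metadata group")
        data = f["data"][...]
        times = f["times"][...]
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_names"][...]]
        sfreq = float(f.attrs["sfreq"])
        grp = f["metadata"]
        columns = list(grp.attrs["columns"])
        meta = {}
        for col in columns:
            if col not in grp:
                raise DataFormatError(f"metadata column '{col}' listed but absent in {path}")
            values = grp[col][...]
            if values.dtype.kind in ("S", "O"):
                values = np.array([v.decode() if isinstance(v, bytes) else v for v in values])
            meta[col] = values
        metadata = pd.DataFrame(meta, columns=columns)
    return EpochSet(data=data, times=times, sfreq=sfreq, metadata=metadata, channel_names=channels)


def write_dataset(epochs: EpochSet, behavior: pd.DataFrame, path: str | Path) -> Path:
    """Write epochs + behavioral table into a dataset directory.

    ``behavior`` must contain at least :data:`BEHAVIOR_COLUMNS`; extra
    columns are preserved.
    """
    missing = [c for c in BEHAVIOR_COLUMNS if c not in behavior.columns]
    if missing:
        raise DataFormatError(f"behavior table is missing required columns: {missing}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_epochs(epochs, path / "epochs.h5")
    behavior.to_csv(path / "behavior.tsv", sep="\t", index=False)
    return path


def read_dataset(path: str | Path) -> tuple[EpochSet, pd.DataFrame]:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    epochs_path = path / "epochs.h5"
    behavior_path = path / "behavior.tsv"
    if not epochs_path.exists():
        raise DataFormatError(f"{epochs_path} not found")
    if not behavior_path.exists():
        raise DataFormatError(f"{behavior_path} not found")
    epochs = read_epochs(epochs_path)
    behavior = pd.read_csv(behavior_path, sep="\t")
    missing = [c for c in BEHAVIOR_COLUMNS if c not in behavior.columns]
    if missing:
        raise DataFormatError(f"behavior table is missing required columns: {missing}")
    return epochs, behavior
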