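"""File I/O for envelope containers, result tables and brain maps.

HDF5 layout (primary container format)::

    /envelopes   float dataset, shape (n_epochs, n_regions, n_samples)
    attrs: fs, epoch_length_s, region_labels

TSV fallback: a directory with one file per epoch (``epoch_0000.tsv`` ...),
regions as columns, plus ``# fs:`` / ``# epoch_length_s:`` header comments;
a single TSV file is read as a one-epoch container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EnvelopeEpochs, ResultTable


class SchemaError(ValueError):
    """Container file does not match the documented schema."""


def write_envelopes(env: EnvelopeEpochs, path: str | Path, format: str = "hdf5") -> Path:
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("envelopes", data=env.values)
            dset.attrs["fs"] = env.fs
            dset.attrs["epoch_length_s"] = env.epoch_length_s
            dset.attrs["region_labels"] = list(env.region_labels)
    elif format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        header = f"# fs: {env.fs}\n# epoch_length_s: {env.epoch_length_s}\n"
        for e in range(env.n_epochs):
            df = pd.DataFrame(env.values[e].T, columns=list(env.region_labels))
            fp = path / f"epoch_{e:04d}.tsv"
            with open(fp, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _read_tsv_epoch(fp: Path) -> tuple[np.ndarray, list[str], dict]:
    meta: dict[str, float] = {}
    with open(fp) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line.lstrip("#").partition(":")
            meta[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return df.to_numpy(dtype=float).T, list(df.columns), meta


def read_envelopes(path: str | Path, format: str = "hdf5") -> EnvelopeEpochs:
    """Read an epoched envelope container.

    Raises
    ------
    SchemaError
        Missing sampling-rate metadata or unknown layout.
    ValueError
        Ragged epochs (shape mismatch between per-epoch TSV files).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "envelopes" not in f:
                raise SchemaError("HDF5 container lacks /envelopes dataset")
            dset = f["envelopes"]
            if "fs" not in dset.attrs:
                raise SchemaError("HDF5 container lacks fs attribute")
            values = dset[()]
            fs = float(dset.attrs["fs"])
            epoch_length_s = float(dset.attrs.get("epoch_length_s", values.shape[2] / fs))
            labels = [
                lbl.decode() if isinstance(lbl, bytes) else str(lbl)
                for lbl in dset.attrs.get("region_labels", [])
            ] or None
        return EnvelopeEpochs(values, fs, labels, epoch_length_s)
    if format == "tsv":
        files = sorted(path.glob("epoch_*.tsv")) if path.is_dir() else [path]
        if not files:
            raise SchemaError(f"no epoch_*.tsv files under {path}")
        epochs, labels0, meta0 = [], None, None
        for fp in files:
            arr, labels, meta = _read_tsv_epoch(fp)
            if labels0 is None:
                labels0, meta0 = labels, meta
            elif labels != labels0:
                raise SchemaError(f"region columns differ in {fp}")
            if epochs and arr.shape != epochs[0].shape:
                raise ValueError(f"ragged epochs: {fp} has shape {arr.shape}")
            epochs.append(arr)
        if "fs" not in (meta0 or {}):
            raise SchemaError("TSV container lacks '# fs:' header")
        values = np.stack(epochs)
        return EnvelopeEpochs(
            values, meta0["fs"], labels0, meta0.get("epoch_length_s")
        )
    raise ValueError(f"unknown format {format!r}")


def write_results(table: ResultTable, path: str | Path) -> Path:
    """Write a ResultTable as TSV (or JSON records if path ends in .json)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(table.df.to_dict(orient="records"), indent=1))
    else:
        table.df.to_csv(path, sep="\t", index=False)
    return path


def read_results(path: str | Path) -> ResultTable:
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame.from_records(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        return ResultTable()
    return ResultTable(df)


def read_brain_map(path: str | Path):
    """Read a regional brain map TSV: columns region, value, x_mm, y_mm, z_mm."""
    from .spatial import BrainMap

    df = pd.read_csv(path, sep="\t")
    required = {"region", "value", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise SchemaError(f"brain-map TSV needs columns {sorted(required)}")
    return BrainMap(
        labels=tuple(df["region"].astype(str)),
        values=df["value"].to_numpy(dtype=float),
        centroids=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
    )


def write_brain_map(bmap, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "region": bmap.labels,
            "value": bmap.values,
            "x_mm": bmap.centroids[:, 0],
            "y_mm": bmap.centroids[:, 1],
            "z_mm": bmap.centroids[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path
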