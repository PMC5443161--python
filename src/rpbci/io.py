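"""Epoch-container I/O.

Two interchangeable on-disk layouts:

* HDF5 (default): datasets ``/data`` (K, N, T) float64, optional
  ``/eog`` (K, n_eog, T), ``/labels`` (K) fixed-width strings over
  {"L","R","I"}, ``/channel_names`` (N) strings, ``/trial_indices``
  (K) int, attributes ``fs`` and ``participant_id``.
* CSV directory: one ``epoch_XXXX.csv`` per epoch (rows = channels,
  columns = samples), a ``manifest.csv`` (filename, label,
  participant_id, trial_index) and ``meta.json`` (fs, channel_names).

Both round-trip an :class:`~rpbci.core.EpochSet` bit-exactly and
preserve epoch order.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import CLASS_ORDER, EpochSet

__all__ = [
    "ContainerFormatError",
    "read_epoch_container",
    "write_epoch_container",
]


class ContainerFormatError(ValueError):
    """The on-disk container violates the layout contract."""


def write_epoch_container(es: EpochSet, path: str | Path) -> None:
    """Write an EpochSet; ``.h5``/``.hdf5`` selects HDF5, else CSV dir."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(es, path)
    else:
        _write_csv_dir(es, path)


def read_epoch_container(path: str | Path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_file():
        return _read_hdf5(path)
    return _read_csv_dir(path)


# ---------------------------------------------------------------- HDF5

def _write_hdf5(es: EpochSet, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.data, dtype="f8")
        if es.eog is not None:
            f.create_dataset("eog", data=es.eog, dtype="f8")
        f.create_dataset("labels", data=np.array(list(es.labels), dtype="S1"))
        f.create_dataset(
            "channel_names",
            data=np.array([c.encode() for c in es.channel_names]))
        f.create_dataset("trial_indices", data=es.trial_indices, dtype="i8")
        f.attrs["fs"] = float(es.fs)
        f.attrs["participant_id"] = es.participant_id


def _read_hdf5(path: Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for key in ("data", "labels", "channel_names"):
            if key not in f:
                raise ContainerFormatError(f"missing dataset /{key}")
        if "fs" not in f.attrs:
            raise ContainerFormatError("missing attribute 'fs'")
        data = f["data"][...]
        labels = np.array([s.decode() for s in f["labels"][...]], dtype=object)
        names = [s.decode() for s in f["channel_names"][...]]
        eog = f["eog"][...] if "eog" in f else None
        tidx = f["trial_indices"][...] if "trial_indices" in f else None
        fs = float(f.attrs["fs"])
        pid = str(f.attrs.get("participant_id", "P1"))
    _validate(data, labels, names)
    return EpochSet(data, labels, names, fs, eog=eog, trial_indices=tidx,
                    participant_id=pid)


# ------------------------------------------------------------- CSV dir

def _write_csv_dir(es: EpochSet, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for k in range(len(es)):
        fname = f"epoch_{k:04d}.csv"
        # %.17g round-trips float64 exactly
        pd.DataFrame(es.data[k]).to_csv(path / fname, index=False,
                                        float_format="%.17g")
        rows.append({
            "filename": fname,
            "label": es.labels[k],
            "participant_id": es.participant_id,
            "trial_index": int(es.trial_indices[k]),
        })
        if es.eog is not None:
            pd.DataFrame(es.eog[k]).to_csv(path / f"eog_{k:04d}.csv",
                                           index=False, float_format="%.17g")
    pd.DataFrame(rows, columns=["filename", "label", "participant_id",
                                "trial_index"]).to_csv(path / "manifest.csv",
                                                       index=False)
    meta = {"fs": float(es.fs), "channel_names": list(es.channel_names),
            "has_eog": es.eog is not None}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _read_csv_dir(path: Path) -> EpochSet:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ContainerFormatError("missing meta.json")
    meta = json.loads(meta_path.read_text())
    if "fs" not in meta:
        raise ContainerFormatError("meta.json lacks 'fs'")
    names = list(meta["channel_names"])
    manifest = pd.read_csv(path / "manifest.csv") if (path / "manifest.csv").exists() else None
    if manifest is None:
        raise ContainerFormatError("missing manifest.csv")
    mats, eogs, labels, tidx = [], [], [], []
    pid = "P1"
    read = lambda p: pd.read_csv(p, float_precision="round_trip")
    for k, row in manifest.iterrows():
        mats.append(read(path / row["filename"]).to_numpy(dtype=float))
        labels.append(str(row["label"]))
        tidx.append(int(row["trial_index"]))
        pid = str(row["participant_id"])
        if meta.get("has_eog"):
            eogs.append(read(path / f"eog_{k:04d}.csv").to_numpy(dtype=float))
    if len(mats) == 0:
        data = np.empty((0, len(names), 0))
        labels_arr = np.empty(0, dtype=object)
        eog = None
    else:
        data = np.stack(mats)
        labels_arr = np.array(labels, dtype=object)
        eog = np.stack(eogs) if eogs else None
    _validate(data, labels_arr, names)
    return EpochSet(data, labels_arr, names, float(meta["fs"]), eog=eog,
                    trial_indices=np.array(tidx, dtype=int) if tidx else None,
                    participant_id=pid)


def _validate(data: np.ndarray, labels: np.ndarray, names: list[str]) -> None:
    if data.ndim != 3:
        raise ContainerFormatError("data must be 3-D (K, N, T)")
    if data.shape[1] != len(names):
        raise ContainerFormatError(
            f"{data.shape[1]} channels but {len(names)} channel names")
    bad = set(labels) - set(CLASS_ORDER)
    if bad:
        raise ContainerFormatError(f"unknown label(s) {sorted(bad)}")
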