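"""HDF5 persistence for recordings and FSI datasets, plus CSV manifests."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from semgshift.features import FSI
from semgshift.grid import ElectrodeGrid
from semgshift.synth import RawRecording

__all__ = ["save_recordings", "load_recordings", "save_fsi_dataset", "load_fsi_dataset", "write_manifest"]


def save_recordings(path, recordings: Iterable[RawRecording]) -> None:
    """One group per trial: the signal array plus scalar attributes."""
    with h5py.File(path, "w") as f:
        trials = f.create_group("trials")
        for i, rec in enumerate(recordings):
            g = trials.create_group(f"trial_{i:04d}")
            g.create_dataset("signal", data=rec.signal, compression="gzip", compression_opts=1)
            g.attrs["gesture"] = rec.gesture
            g.attrs["repetition"] = rec.repetition
            g.attrs["center_sample"] = rec.center_sample
            g.attrs["fs_hz"] = rec.fs_hz
            g.attrs["n_rows"] = rec.grid.n_rows
            g.attrs["n_cols"] = rec.grid.n_cols
            g.attrs["pitch_mm"] = rec.grid.pitch_mm


def load_recordings(path) -> list[RawRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f["trials"]):
            g = f["trials"][name]
            grid = ElectrodeGrid(
                n_rows=int(g.attrs["n_rows"]),
                n_cols=int(g.attrs["n_cols"]),
                pitch_mm=float(g.attrs["pitch_mm"]),
            )
            out.append(
                RawRecording(
                    signal=g["signal"][...],
                    grid=grid,
                    gesture=int(g.attrs["gesture"]),
                    repetition=int(g.attrs["repetition"]),
                    center_sample=int(g.attrs["center_sample"]),
                    fs_hz=float(g.attrs["fs_hz"]),
                )
            )
    return out


def save_fsi_dataset(path, images: np.ndarray, labels: np.ndarray, provenance: pd.DataFrame | None = None) -> None:
    """Image stack + parallel label vector (+ optional provenance table)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=np.asarray(images, dtype=np.float32), compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        if provenance is not None:
            g = f.create_group("provenance")
            for col in provenance.columns:
                g.create_dataset(col, data=provenance[col].to_numpy())


def load_fsi_dataset(path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame | None]:
    with h5py.File(path, "r") as f:
        images = f["images"][...]
        labels = f["labels"][...]
        prov = None
        if "provenance" in f:
            prov = pd.DataFrame({col: f["provenance"][col][...] for col in f["provenance"]})
    return images, labels, prov


def write_manifest(path, recordings: Sequence[RawRecording]) -> None:
    """Plain-text CSV listing of trials."""
    rows = [
        {
            "trial": i,
            "gesture": rec.gesture,
            "repetition": rec.repetition,
            "center_sample": rec.center_sample,
            "n_channels": rec.signal.shape[0],
            "n_samples": rec.signal.shape[1],
        }
        for i, rec in enumerate(recordings)
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
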