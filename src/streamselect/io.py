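"""HDF5 / CSV persistence for datasets, matrices and trial metadata."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .data import EpochsData
from .decoding import GeneralizationMatrix


def _write_epochs(group: h5py.Group, epochs: EpochsData) -> None:
    group.create_dataset("data", data=epochs.data)
    group.create_dataset("times", data=epochs.times)
    group.attrs["sfreq"] = epochs.sfreq


def _read_epochs(group: h5py.Group, meta: pd.DataFrame | None = None) -> EpochsData:
    return EpochsData(data=group["data"][()], times=group["times"][()],
                      sfreq=float(group.attrs["sfreq"]), meta=meta)


def write_dataset_h5(
    path: str,
    localizer: EpochsData,
    rsvp: EpochsData,
    seed: int,
    stim_onsets: np.ndarray | None = None,
) -> None:
    """Write one subject's simulated session (groups /localizer, /rsvp)."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = seed
        _write_epochs(f.create_group("localizer"), localizer)
        g = f.create_group("rsvp")
        _write_epochs(g, rsvp)
        if stim_onsets is not None:
            g.attrs["stim_onsets"] = np.asarray(stim_onsets, dtype=float)


def read_dataset_h5(
    path: str,
    localizer_meta: pd.DataFrame | None = None,
    rsvp_meta: pd.DataFrame | None = None,
) -> dict:
    """Read a session written by :func:`write_dataset_h5`."""
    with h5py.File(path, "r") as f:
        out = {
            "seed": int(f.attrs["seed"]),
            "localizer": _read_epochs(f["localizer"], localizer_meta),
            "rsvp": _read_epochs(f["rsvp"], rsvp_meta),
        }
        if "stim_onsets" in f["rsvp"].attrs:
            out["stim_onsets"] = np.asarray(f["rsvp"].attrs["stim_onsets"])
    return out


def write_trial_info_csv(path: str, trial_info: pd.DataFrame) -> None:
    trial_info.to_csv(path, index=False)


def read_trial_info_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrices_h5(path: str, matrices: dict[str, GeneralizationMatrix]) -> None:
    """Write named generalization matrices under /matrices/<condition>."""
    with h5py.File(path, "w") as f:
        root = f.create_group("matrices")
        for name, mat in matrices.items():
            g = root.create_group(name)
            g.create_dataset("values", data=mat.values)
            g.create_dataset("train_times", data=mat.train_times)
            g.create_dataset("test_times", data=mat.test_times)
            g.attrs["chance"] = mat.chance


def read_matrices_h5(path: str) -> dict[str, GeneralizationMatrix]:
    out: dict[str, GeneralizationMatrix] = {}
    with h5py.File(path, "r") as f:
        for name, g in f["matrices"].items():
            out[name] = GeneralizationMatrix(
                values=g["values"][()], train_times=g["train_times"][()],
                test_times=g["test_times"][()], chance=float(g.attrs["chance"]),
            )
    return out


def matrix_long_csv(
    matrices: dict[str, GeneralizationMatrix], subject: int | None = None
) -> pd.DataFrame:
    """Long-format export (train_ms, test_ms, condition, subject, value)."""
    rows = []
    for name, mat in matrices.items():
        tr, te = np.meshgrid(mat.train_times, mat.test_times, indexing="ij")
        rows.append(pd.DataFrame({
            "train_ms": tr.ravel(), "test_ms": te.ravel(),
            "condition": name, "subject": subject,
            "value": mat.values.ravel(),
        }))
    return pd.concat(rows, ignore_index=True)
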