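"""Serialization: weights and rate traces to HDF5, tidy tables to CSV/JSON.

The HDF5 container stores the six weight matrices as datasets named
W_EE ... W_IF, optional rate/potential traces (r_E, r_I, u_E, u_I), and the
integration step and other parameters as attributes.  Metric tables are
written as tidy CSV with a JSON sidecar recording the computation parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .network import BLOCKS, WeightSet

__all__ = [
    "save_weights",
    "load_weights",
    "save_rate_traces",
    "weights_to_csv",
    "write_table",
]


def save_weights(path, w: WeightSet, *, attrs: dict | None = None) -> None:
    """Write a WeightSet to an HDF5 file (datasets W_EE ... W_IF)."""
    with h5py.File(path, "w") as f:
        for b in BLOCKS:
            ds = f.create_dataset(f"W_{b}", data=w.block(b))
            ds.attrs["plastic"] = bool(w.plastic[b])
        f.attrs["exclude_autapses"] = w.exclude_autapses
        for k, v in (attrs or {}).items():
            if v is not None:
                f.attrs[k] = v


def load_weights(path) -> WeightSet:
    with h5py.File(path, "r") as f:
        mats = [f[f"W_{b}"][...] for b in BLOCKS]
        plastic = {b: bool(f[f"W_{b}"].attrs.get("plastic", True)) for b in BLOCKS}
        excl = bool(f.attrs.get("exclude_autapses", True))
    return WeightSet(*mats, plastic=plastic, exclude_autapses=excl)


def save_rate_traces(path, r_E: np.ndarray, r_I: np.ndarray, dt: float,
                     *, u_E: np.ndarray | None = None,
                     u_I: np.ndarray | None = None,
                     attrs: dict | None = None) -> None:
    """Store per-step rate (and optionally potential) traces with dt attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("r_E", data=np.asarray(r_E))
        f.create_dataset("r_I", data=np.asarray(r_I))
        if u_E is not None:
            f.create_dataset("u_E", data=np.asarray(u_E))
        if u_I is not None:
            f.create_dataset("u_I", data=np.asarray(u_I))
        f.attrs["dt"] = dt
        for k, v in (attrs or {}).items():
            if v is not None:
                f.attrs[k] = v


def weights_to_csv(directory, w: WeightSet) -> None:
    """Flat CSV export, one file per weight matrix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for b in BLOCKS:
        np.savetxt(directory / f"W_{b}.csv", w.block(b), delimiter=",")


def write_table(path, frame: pd.DataFrame, params: dict | None = None) -> None:
    """Tidy CSV plus a JSON sidecar with the computation parameters."""
    path = Path(path)
    frame.to_csv(path, index=False)
    if params is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(params, indent=2, default=str))
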