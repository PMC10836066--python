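"""Sweep-set and table persistence (CSV and HDF5)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import Sweep


def write_sweeps_csv(sweeps: list[Sweep], path):
    """One CSV per sweep set: columns time_ms, sweep_<id>... plus metadata row."""
    path = Path(path)
    data = {"time_ms": sweeps[0].time}
    for sw in sweeps:
        data[f"sweep_{sw.sweep_id}"] = sw.current
    df = pd.DataFrame(data)
    header = (f"# stim_time_ms={sweeps[0].stim_time} holding_mv={sweeps[0].holding} "
              f"fs_khz={sweeps[0].fs_khz}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_sweeps_csv(path) -> list[Sweep]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    out = []
    for col in df.columns:
        if not col.startswith("sweep_"):
            continue
        out.append(Sweep(current=df[col].to_numpy(),
                         fs_khz=float(meta["fs_khz"]),
                         stim_time=float(meta["stim_time_ms"]),
                         holding=float(meta["holding_mv"]),
                         sweep_id=int(col.split("_")[1])))
    return out


def write_sweeps_hdf5(sweeps_by_holding: dict, path):
    """HDF-style container: one group per holding potential."""
    import h5py

    with h5py.File(path, "w") as f:
        for holding, sweeps in sweeps_by_holding.items():
            grp = f.create_group(f"holding_{holding:+.0f}mV")
            grp.attrs["holding_mv"] = holding
            grp.attrs["stim_time_ms"] = sweeps[0].stim_time
            grp.attrs["fs_khz"] = sweeps[0].fs_khz
            grp.create_dataset("current_pa",
                               data=np.stack([s.current for s in sweeps]),
                               compression="gzip")


def read_sweeps_hdf5(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            grp = f[name]
            holding = float(grp.attrs["holding_mv"])
            arr = grp["current_pa"][...]
            out[holding] = [Sweep(current=arr[i], fs_khz=float(grp.attrs["fs_khz"]),
                                  stim_time=float(grp.attrs["stim_time_ms"]),
                                  holding=holding, sweep_id=i)
                            for i in range(arr.shape[0])]
    return out


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, provenance: str | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# provenance={provenance}\n")
        df.to_csv(fh, index=False)
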