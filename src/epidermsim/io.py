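"""Snapshot and manifest serialisation.

One CSV per snapshot (columns: id, x, y, z, a, c, state, age_in_state, ca;
comma-separated, header row, '.' decimal) plus a run-level JSON manifest with
the config echo, its hash and the per-snapshot counters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .cell_model import CellState
from .mechanics import SimConfig, SimState

SNAPSHOT_COLUMNS = ["id", "x", "y", "z", "a", "c", "state", "age_in_state", "ca"]


def snapshot_frame(state: SimState) -> pd.DataFrame:
    return pd.DataFrame({
        "id": state.ids,
        "x": state.pos[:, 0], "y": state.pos[:, 1], "z": state.pos[:, 2],
        "a": state.aa, "c": state.cc,
        "state": [CellState(int(s)).name for s in state.state],
        "age_in_state": state.age,
        "ca": state.ca,
    })


def write_snapshot_csv(state: SimState, path) -> None:
    snapshot_frame(state).to_csv(path, index=False)


def read_snapshot_csv(path) -> SimState:
    df = pd.read_csv(path)
    n = len(df)
    state_codes = np.array([int(CellState[s]) for s in df["state"]], np.uint8)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    return SimState(pos, df["a"].to_numpy(float), df["c"].to_numpy(float),
                    state_codes, df["age_in_state"].to_numpy(float),
                    df["ca"].to_numpy(float), pos[:, :2].copy(),
                    df["id"].to_numpy(np.int64))


def write_run(out_dir, config: SimConfig, snapshots: List[SimState]) -> Path:
    """Write every snapshot CSV plus the run manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, snap in enumerate(snapshots):
        name = f"snapshot_{i:04d}.csv"
        write_snapshot_csv(snap, out / name)
        entries.append({"file": name, "t_h": snap.t, "n_cells": snap.n_cells,
                        "births": snap.births, "removals": snap.removals,
                        **snap.counts_by_state()})
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash,
                "snapshots": entries}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
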