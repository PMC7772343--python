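"""Cell-table and metadata I/O.

The interchange format is a delimited table, one row per cell, with columns
``id, x, y, z, radius, etype, parent_id`` (``etype`` mandatory for analysis
inputs; ``radius``/``parent_id`` optional for experimental-style tables),
plus an optional JSON sidecar with config hash, seed, time and cell count.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import SpheroidState
from .types import TYPE_NAMES, UNASSIGNED, etype_codes

__all__ = ["state_to_table", "read_cell_table", "write_cell_table",
           "write_snapshot", "config_hash"]

_ETYPE_LABEL = {**{i: name for i, name in enumerate(TYPE_NAMES)},
                UNASSIGNED: "UNASSIGNED"}


def state_to_table(state: SpheroidState) -> pd.DataFrame:
    """Snapshot of a simulator state as the standard cell table."""
    return pd.DataFrame({
        "id": state.ids,
        "x": state.pos[:, 0],
        "y": state.pos[:, 1],
        "z": state.pos[:, 2],
        "radius": state.radius,
        "etype": [_ETYPE_LABEL[int(e)] for e in state.etype],
        "parent_id": state.parent,
    })


def write_cell_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table; validates presence of coordinates and etype."""
    table = pd.read_csv(path)
    missing = {"x", "y", "z", "etype"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    etype_codes(table["etype"])  # validates labels
    return table


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_snapshot(state: SpheroidState, path, config: dict | None = None,
                   seed: int | None = None) -> None:
    """Write the cell table plus a JSON metadata sidecar (<path>.meta.json)."""
    path = Path(path)
    write_cell_table(state_to_table(state), path)
    meta = {
        "n_cells": int(state.n_cells),
        "time": float(state.time),
        "seed": seed,
        "config_hash": None if config is None else config_hash(config),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
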