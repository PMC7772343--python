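"""Shared domain types: expression types and the single-cell record.

The four expression types classify cells by high/low NANOG and GATA6
expression (N+G+, N-G-, N+G-, N-G+).  Internally they are small integer
codes so that simulation state can live in flat numpy arrays; the canonical
ordering used throughout for proportion vectors and composition matrices is
(NpGp, NnGn, NpGn, NnGp).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "ExpressionType",
    "TYPE_NAMES",
    "N_TYPES",
    "UNASSIGNED",
    "Cell",
    "etype_codes",
]


class ExpressionType(IntEnum):
    """NANOG/GATA6 expression class of a cell."""

    NpGp = 0  # NANOG+ GATA6+ (double positive)
    NnGn = 1  # NANOG- GATA6- (double negative)
    NpGn = 2  # NANOG+ GATA6- (epiblast-like)
    NnGp = 3  # NANOG- GATA6+ (primitive-endoderm-like)


TYPE_NAMES: tuple[str, ...] = tuple(t.name for t in ExpressionType)
N_TYPES: int = len(TYPE_NAMES)

#: etype code of a cell before the fate-assignment stage (symbol-free stand-in
#: for "undifferentiated"); never a valid member of :class:`ExpressionType`.
UNASSIGNED: int = -1

_NAME_TO_CODE = {name: i for i, name in enumerate(TYPE_NAMES)}
_NAME_TO_CODE["UNASSIGNED"] = UNASSIGNED


@dataclass
class Cell:
    """A single simulated cell (scalar view; the simulator stores arrays)."""

    id: int
    pos: np.ndarray
    radius: float
    etype: int = UNASSIGNED
    parent_id: int | None = None

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ValueError("Cell.pos must be a 3-vector")
        if self.radius <= 0:
            raise ValueError("Cell.radius must be positive")


def etype_codes(values) -> np.ndarray:
    """Coerce an etype column (names or integer codes) to int codes.

    Accepts any iterable of strings in TYPE_NAMES / "UNASSIGNED" or integers
    in {-1, 0..3}; raises ValueError on anything else.
    """
    arr = np.asarray(values)
    if arr.dtype.kind in "iu":
        out = arr.astype(np.int8)
    else:
        try:
            out = np.array([_NAME_TO_CODE[str(v)] for v in arr], dtype=np.int8)
        except KeyError as e:
            raise ValueError(f"unknown expression type label: {e.args[0]!r}") from e
    bad = (out < UNASSIGNED) | (out >= N_TYPES)
    if np.any(bad):
        raise ValueError(f"invalid expression type codes: {np.unique(out[bad])}")
    return out
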