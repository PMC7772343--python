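"""Shared fixtures: simulated H1 snapshot sets reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from icmsim import MechanicsParams, assign_initial_fates, heredity_model, inherit
from icmsim.core_model import init_spheroid, run_until_count

#: synthetic stand-in target proportions (order NpGp, NnGn, NpGn, NnGp)
P_T1 = np.array([0.15, 0.10, 0.40, 0.35])
P_T2 = np.array([0.07, 0.05, 0.35, 0.53])


def simulate_h1_snapshot(seed: int, t0: int, t1: int = 441,
                         init_count: int = 200):
    """One H1 repetition: init -> grow to t0 -> assign -> grow to t1.

    Under strict heredity the back-solved initial proportions equal the
    target proportions, so P_T1 is assigned directly at t0.
    Returns (positions, etype codes) at the t1 snapshot.
    """
    params = MechanicsParams()
    model = heredity_model("H1")
    state = init_spheroid(init_count, params, seed=seed)
    if t0 > state.n_cells:
        run_until_count(state, params, t0)
    assign_initial_fates(state, P_T1)
    run_until_count(state, params, t1,
                    lambda m, rng: inherit(m, model, rng))
    return state.pos.copy(), state.etype.copy()


@pytest.fixture(scope="session")
def h1_snapshot_sets():
    """20 H1 repetitions per fate-assignment count t0 in {200, 300, 400},
    each recorded at the 441-cell snapshot."""
    out = {}
    for t0 in (200, 300, 400):
        out[t0] = [simulate_h1_snapshot(seed=1000 * t0 + rep, t0=t0)
                   for rep in range(20)]
    return out
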