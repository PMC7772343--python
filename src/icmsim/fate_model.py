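"""Cell-fate assignment, heredity hypotheses and proportion dynamics.

At the fate-assignment stage (t0, triggered by cell count) every cell draws
an expression type i.i.d. from an initial proportion vector.  At each
subsequent division the two daughters draw their types from the mother's
daughter-type distribution, defined by one of four nested heredity
hypotheses:

* H1 — strict heredity: both daughters keep the mother's type.
* H2 — NpGp mothers may additionally produce NnGp daughters.
* H3 — more switches allowed.  Two published readings of the edge set exist
  and both are shipped: the default ("results") adds NnGn->NpGp, NpGp->NpGn,
  NpGp->NnGp and NpGn->NnGp; the narrower "methods" variant adds only
  NpGn->NnGp on top of H2.
* H4 — H3 plus a small reverse flux NnGp->NpGn, closing the
  NpGn<->NnGp exchange.

Because every fate divides at the same constant rate, expected type counts n
follow dn/dt = lam (D^T - I) n with D the daughter matrix
(D[i][j] = expected type-j daughters per division of a type-i mother), and
proportions follow dp/dt = lam (D^T - 2I) p.  Reparametrising time by
s = ln(cell count) removes lam, so proportions between two population sizes
are connected by a matrix exponential in ln(n_to/n_from).  This linear flow
is used forwards (predicting t1/t2 proportions) and backwards (recovering
the t0 proportions that will hit a target at t1), and as the objective of
the transition-rate fit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .errors import FitError, InfeasibleHypothesisError
from .types import N_TYPES, TYPE_NAMES, UNASSIGNED, ExpressionType

__all__ = [
    "HeredityModel",
    "heredity_model",
    "HYPOTHESIS_EDGES",
    "inherit",
    "daughter_matrix",
    "assign_initial_fates",
    "propagate_proportions",
    "back_solve_t0",
    "fit_transition_rates",
    "simulate_lineage_proportions",
    "as_proportions",
]

_T = ExpressionType

#: short codes used in rate names: pp=NpGp, nn=NnGn, pn=NpGn, np=NnGp
_CODE = {"pp": _T.NpGp, "nn": _T.NnGn, "pn": _T.NpGn, "np": _T.NnGp}


def _edge(name: str) -> tuple[int, int]:
    src, dst = name.removeprefix("q_").split("_to_")
    return int(_CODE[src]), int(_CODE[dst])


# Rate-parameter names per hypothesis, in canonical order.
HYPOTHESIS_EDGES: dict[str, tuple[str, ...]] = {
    "H1": (),
    "H2": ("q_pp_to_np",),
    "H3": ("q_pp_to_np", "q_nn_to_pp", "q_pp_to_pn", "q_pn_to_np"),
    "H3_methods": ("q_pp_to_np", "q_pn_to_np"),
    "H4": ("q_pp_to_np", "q_nn_to_pp", "q_pp_to_pn", "q_pn_to_np", "q_np_to_pn"),
}


@dataclass(frozen=True)
class HeredityModel:
    """A heredity hypothesis with concrete switch probabilities.

    ``daughter_dist[i]`` is the distribution over a single daughter's type
    for a type-i mother; with ``forced_asymmetric`` the same probabilities
    are realised by switching exactly one (coin-flipped) daughter instead of
    sampling both independently.
    """

    hypothesis: str
    rates: Mapping[str, float]
    daughter_dist: np.ndarray
    allowed_edges: frozenset
    forced_asymmetric: bool = False

    def __post_init__(self):
        dist = np.asarray(self.daughter_dist, dtype=float)
        if dist.shape != (N_TYPES, N_TYPES):
            raise ValueError("daughter_dist must be 4x4")
        if np.any(dist < -1e-12):
            raise ValueError("daughter_dist entries must be non-negative")
        if not np.allclose(dist.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("daughter_dist rows must sum to 1")
        off = dist.copy()
        np.fill_diagonal(off, 0.0)
        for i, j in zip(*np.nonzero(off > 1e-15)):
            if (int(i), int(j)) not in self.allowed_edges:
                raise ValueError(
                    f"probability mass on forbidden switch "
                    f"{TYPE_NAMES[i]}->{TYPE_NAMES[j]} under {self.hypothesis}"
                )
        object.__setattr__(self, "daughter_dist", dist)

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "forced_asymmetric": self.forced_asymmetric,
            "rates": {k: float(v) for k, v in self.rates.items()},
        }


def heredity_model(
    hypothesis: str,
    rates: Mapping[str, float] | None = None,
    forced_asymmetric: bool = False,
) -> HeredityModel:
    """Build a :class:`HeredityModel` for ``hypothesis``.

    ``rates`` maps rate names (e.g. ``q_pp_to_np``) to switch probabilities
    in [0, 1]; omitted rates default to 0, which reduces every hypothesis
    exactly to H1.  ``hypothesis`` may be "H1".."H4" or "H3_methods".
    """
    if hypothesis not in HYPOTHESIS_EDGES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; "
                         f"choose from {sorted(HYPOTHESIS_EDGES)}")
    names = HYPOTHESIS_EDGES[hypothesis]
    rates = dict(rates or {})
    unknown = set(rates) - set(names)
    if unknown:
        raise ValueError(f"rates {sorted(unknown)} not allowed under {hypothesis}")
    full = {name: float(rates.get(name, 0.0)) for name in names}
    for name, q in full.items():
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"{name}={q} outside [0, 1]")
    dist = np.eye(N_TYPES)
    for name, q in full.items():
        i, j = _edge(name)
        dist[i, i] -= q
        dist[i, j] += q
    if np.any(np.diag(dist) < -1e-12):
        raise ValueError("total switch probability out of a mother type exceeds 1")
    edges = frozenset(_edge(name) for name in names)
    return HeredityModel(hypothesis=hypothesis, rates=full, daughter_dist=dist,
                         allowed_edges=edges, forced_asymmetric=forced_asymmetric)


def _sample(dist_row: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(dist_row), rng.random(), side="right"))


def inherit(mother_type: int, model: HeredityModel,
            rng: np.random.Generator) -> tuple[int, int]:
    """Draw the two daughter types for a division of a ``mother_type`` cell."""
    m = int(mother_type)
    if not 0 <= m < N_TYPES:
        raise ValueError(f"invalid mother type code {mother_type}")
    row = model.daughter_dist[m]
    if not model.forced_asymmetric:
        return _sample(row, rng), _sample(row, rng)
    # forced-asymmetric reading: at most one daughter switches
    q_total = 1.0 - row[m]
    if q_total <= 0 or rng.random() >= q_total:
        return m, m
    off = row.copy()
    off[m] = 0.0
    switched = _sample(off / q_total, rng)
    return (switched, m) if rng.random() < 0.5 else (m, switched)


def daughter_matrix(model: HeredityModel) -> np.ndarray:
    """Expected daughters per division: D[i][j] type-j daughters of a type-i mother.

    Rows sum to exactly 2.  Under the forced-asymmetric variant at most one
    daughter switches, so the expectation differs from the independent case.
    """
    if model.forced_asymmetric:
        D = model.daughter_dist.copy()
        np.fill_diagonal(D, 0.0)
        np.fill_diagonal(D, 2.0 - D.sum(axis=1))
        return D
    return 2.0 * model.daughter_dist


def as_proportions(p, *, atol: float = 1e-8) -> np.ndarray:
    """Validate and return a 4-entry proportion vector (canonical type order)."""
    p = np.asarray(p, dtype=float)
    if p.shape != (N_TYPES,):
        raise ValueError("proportion vector must have 4 entries "
                         "(order NpGp, NnGn, NpGn, NnGp)")
    if np.any(p < -atol) or np.any(p > 1 + atol):
        raise ValueError(f"proportions outside [0, 1]: {p}")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"proportions sum to {p.sum()}, expected 1")
    return np.clip(p, 0.0, 1.0)


def assign_initial_fates(state, p0, rng: np.random.Generator | None = None):
    """Assign each cell's type i.i.d. from ``p0`` (position-independent).

    Errors if any cell already has a fate; uses the state's own RNG unless an
    explicit generator is supplied.  Mutates and returns ``state``.
    """
    p0 = as_proportions(p0)
    if np.any(state.etype != UNASSIGNED):
        raise ValueError("assign_initial_fates called on already-assigned cells")
    gen = rng if rng is not None else state.rng
    draws = gen.random(state.n_cells)
    state.etype = np.searchsorted(np.cumsum(p0), draws,
                                  side="right").astype(np.int8)
    state.etype = np.clip(state.etype, 0, N_TYPES - 1)  # guard p0 rounding
    state.event_log.append((state.time, "fate_assignment", tuple(np.bincount(
        state.etype, minlength=N_TYPES).tolist())))
    return state


def _flow_matrix(D: np.ndarray, n_from: int, n_to: int) -> np.ndarray:
    A = D.T - 2.0 * np.eye(N_TYPES)
    return expm(A * np.log(n_to / n_from))


def propagate_proportions(p, D: np.ndarray, n_from: int, n_to: int) -> np.ndarray:
    """Forward-flow proportions from population size n_from to n_to."""
    p = as_proportions(p)
    if not 1 <= n_from <= n_to:
        raise ValueError("need n_to >= n_from >= 1 (use back_solve_t0 backwards)")
    out = _flow_matrix(np.asarray(D, float), n_from, n_to) @ p
    return as_proportions(out)


def back_solve_t0(p_t1, D: np.ndarray, n0: int, n1: int,
                  atol: float = 1e-9) -> np.ndarray:
    """Invert the proportion flow: the p0 at n0 cells that reaches p_t1 at n1.

    Raises :class:`InfeasibleHypothesisError` if the mathematical inverse
    leaves the probability simplex (the target is unreachable from any valid
    initial proportion under this heredity model); never clips silently.
    """
    p_t1 = as_proportions(p_t1)
    if not 1 <= n0 <= n1:
        raise ValueError("need n1 >= n0 >= 1")
    p0 = _flow_matrix(np.asarray(D, float), n1, n0) @ p_t1  # log ratio < 0
    if np.any(p0 < -atol) or np.any(p0 > 1 + atol):
        bad = int(np.argmax(np.maximum(-p0, p0 - 1)))
        raise InfeasibleHypothesisError(
            f"back-solved t0 proportion for {TYPE_NAMES[bad]} is {p0[bad]:.6g}, "
            "outside [0, 1]: target proportions unreachable under this hypothesis",
            proportions=p0, offending_index=bad)
    return as_proportions(np.clip(p0, 0.0, 1.0))


def _rate_objective(theta, names, hypothesis, p_t1, p_t2, n0, n1, n2,
                    forced_asymmetric):
    model = heredity_model(hypothesis, dict(zip(names, theta)),
                           forced_asymmetric=forced_asymmetric)
    D = daughter_matrix(model)
    try:
        p0 = back_solve_t0(p_t1, D, n0, n1)
    except InfeasibleHypothesisError as e:
        violation = float(np.sum(np.maximum(-e.proportions, 0.0)
                                 + np.maximum(e.proportions - 1.0, 0.0)))
        return 1.0 + violation
    p2 = propagate_proportions(p0, D, n0, n2)
    return float(np.sum((p2 - p_t2) ** 2))


def fit_transition_rates(
    hypothesis: str,
    p_t1,
    p_t2,
    n0: int,
    n1: int,
    n2: int,
    forced_asymmetric: bool = False,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[HeredityModel, dict]:
    """Fit the free switch probabilities of ``hypothesis`` to target proportions.

    The initial proportions are always back-solved so the flow matches p_t1
    exactly at n1 cells; the rates then minimise the squared deviation of the
    propagated proportions from p_t2 at n2 cells (bound-constrained to
    [0, 1], deterministic multi-start).  For the nested hypotheses the fit of
    the next-simpler hypothesis is embedded as an extra start, so added
    complexity can only reduce the residual.
    """
    if hypothesis == "H1":
        raise ValueError("H1 has no free parameters to fit")
    if hypothesis not in HYPOTHESIS_EDGES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    p_t1 = as_proportions(p_t1)
    p_t2 = as_proportions(p_t2)
    names = HYPOTHESIS_EDGES[hypothesis]
    k = len(names)

    starts = [np.zeros(k)]
    parent = {"H3": "H2", "H3_methods": "H2", "H4": "H3"}.get(hypothesis)
    if parent is not None:
        sub_model, _ = fit_transition_rates(
            parent, p_t1, p_t2, n0, n1, n2,
            forced_asymmetric=forced_asymmetric, n_starts=n_starts, seed=seed)
        embedded = np.array([sub_model.rates.get(name, 0.0) for name in names])
        starts.append(embedded)
    rng = np.random.default_rng(seed)
    starts.extend(rng.uniform(0.0, 0.3, size=(max(0, n_starts - len(starts)), k)))

    args = (names, hypothesis, p_t1, p_t2, n0, n1, n2, forced_asymmetric)
    best = None
    for x0 in starts:
        res = minimize(_rate_objective, x0, args=args, method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * k,
                       options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("transition-rate optimisation failed",
                       best_rates=None if best is None
                       else dict(zip(names, best.x)))
    rates = dict(zip(names, np.clip(best.x, 0.0, 1.0)))
    model = heredity_model(hypothesis, rates, forced_asymmetric=forced_asymmetric)
    info = {"residual": float(best.fun), "n_starts": len(starts),
            "converged": bool(best.success)}
    return model, info


def simulate_lineage_proportions(
    p0,
    model: HeredityModel,
    n0: int,
    n1: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pure branching-process realisation of the proportion dynamics.

    Starts from n0 cells typed i.i.d. from p0; repeatedly picks a uniformly
    random cell to divide (all fates share one constant division rate) and
    replaces it by two daughters drawn via :func:`inherit`, until the
    population reaches n1.  Returns the realised proportion vector — the
    stochastic counterpart of :func:`propagate_proportions`, with no
    mechanics involved.
    """
    p0 = as_proportions(p0)
    if not 1 <= n0 <= n1:
        raise ValueError("need n1 >= n0 >= 1")
    types = list(np.searchsorted(np.cumsum(p0), rng.random(n0), side="right")
                 .astype(int))
    while len(types) < n1:
        idx = int(rng.integers(len(types)))
        d1, d2 = inherit(types[idx], model, rng)
        types[idx] = d1
        types.append(d2)
    counts = np.bincount(np.array(types), minlength=N_TYPES)
    return counts / counts.sum()
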