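"""Off-lattice centre-based spheroid simulator.

Cells are spheres with a position, a radius and an expression type.  Pairs
of cells interact through a Morse-type force: repulsive when their centres
are closer than the sum of their radii (limited compressibility), attractive
between contact distance and a cutoff of ``sigma * r_i`` (adhesion), zero
beyond.  Motion is overdamped — velocities equal net force — integrated with
explicit Euler.  Radii relax towards a maximum size ``r_star`` with rate
``k_growth``; the radius update uses the exact exponential flow of that
linear ODE, so it matches the closed-form solution to machine precision for
any step size.

Division is a stochastic process depending on the radius only: a cell whose
radius exceeds ``div_threshold_frac * r_star`` divides with constant hazard
``div_rate``.  At division the mother keeps its position, both daughters get
radius ``r * 2**(-1/3)`` (total volume exactly conserved) and the new cell is
offset by a small random vector.  Daughter expression types are produced by
an injected heredity callback (see :mod:`icmsim.fate_model`); undifferentiated
mothers produce undifferentiated daughters.

Note one deliberate quirk kept from the model definition: the interaction
cutoff ``d < sigma * r_i`` depends on the radius of the cell the force acts
on, so for unequal radii the force field is not reciprocal in the band
between ``sigma*r_i`` and ``sigma*r_k``.  ``symmetrise_cutoff=True`` replaces
the rule by ``d < sigma * min(r_i, r_k)`` (pairwise all-or-nothing).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidGeometryError, NonProgressError, StepInstabilityError
from .types import UNASSIGNED, Cell

__all__ = [
    "MechanicsParams",
    "SpheroidState",
    "pair_force_magnitude",
    "net_force",
    "net_forces",
    "grow_step",
    "maybe_divide",
    "step",
    "relax",
    "init_spheroid",
    "run_until_count",
    "max_overlap_fraction",
]

#: centres closer than this are treated as coincident and jittered apart
_COINCIDENT_TOL = 1e-9

#: volume-conserving radius factor at division, (1/2)^(1/3)
HALF_CBRT = 0.5 ** (1.0 / 3.0)

InheritFn = Callable[[int, np.random.Generator], tuple[int, int]]


@dataclass(frozen=True)
class MechanicsParams:
    """Mechanical, growth and division parameters (model units)."""

    F0: float = 1.0              # interaction strength
    a: float = 0.6               # spatial decay of the interaction
    sigma: float = 4.0           # cutoff multiple of the focal cell radius
    k_growth: float = 1.0        # growth rate towards r_star
    r_star: float = 1.0          # maximum cell radius
    dt: float = 0.002            # Euler time step
    delta_frac: float = 0.1      # daughter offset as fraction of its radius
    div_threshold_frac: float = 0.95  # radius fraction gating the division hazard
    div_rate: float = 1.0        # division hazard per unit time above threshold
    symmetrise_cutoff: bool = False

    def __post_init__(self):
        for name in ("F0", "a", "k_growth", "r_star", "dt", "div_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MechanicsParams.{name} must be > 0")
        if self.sigma <= 2:
            raise ValueError("MechanicsParams.sigma must exceed 2")
        if not 0 < self.div_threshold_frac <= 1:
            raise ValueError("div_threshold_frac must lie in (0, 1]")
        if self.delta_frac <= 0:
            raise ValueError("delta_frac must be > 0")


@dataclass
class SpheroidState:
    """Complete simulator state: flat per-cell arrays plus clock and RNG."""

    pos: np.ndarray                 # (n, 3) float64
    radius: np.ndarray              # (n,) float64
    etype: np.ndarray               # (n,) int8, UNASSIGNED before fate stage
    ids: np.ndarray                 # (n,) int64, unique, insertion-ordered
    parent: np.ndarray              # (n,) int64, -1 for founder cells
    time: float
    rng: np.random.Generator
    next_id: int
    event_log: list = field(default_factory=list)
    # Verlet candidate-pair cache (performance only; never affects results
    # beyond float summation order): pairs within cutoff + margin, valid
    # while accumulated drift stays below half the margin.
    _pairs: np.ndarray | None = field(default=None, repr=False, compare=False)
    _pairs_n: int = field(default=-1, repr=False, compare=False)
    _drift: float = field(default=0.0, repr=False, compare=False)

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    def cell(self, index: int) -> Cell:
        """Scalar view of one cell (by array index, not id)."""
        pid = int(self.parent[index])
        return Cell(
            id=int(self.ids[index]),
            pos=self.pos[index].copy(),
            radius=float(self.radius[index]),
            etype=int(self.etype[index]),
            parent_id=None if pid < 0 else pid,
        )

    def copy(self) -> "SpheroidState":
        return SpheroidState(
            pos=self.pos.copy(),
            radius=self.radius.copy(),
            etype=self.etype.copy(),
            ids=self.ids.copy(),
            parent=self.parent.copy(),
            time=self.time,
            rng=_copy_rng(self.rng),
            next_id=self.next_id,
            event_log=list(self.event_log),
        )

    def invalidate_cache(self) -> None:
        self._pairs = None
        self._pairs_n = -1
        self._drift = 0.0


def _copy_rng(rng: np.random.Generator) -> np.random.Generator:
    bg = type(rng.bit_generator)()
    bg.state = rng.bit_generator.state
    return np.random.Generator(bg)


def pair_force_magnitude(r_i: float, r_k: float, d: float, params: MechanicsParams) -> float:
    """Morse force magnitude on cell i from cell k at centre distance d.

    Positive values repel, negative attract; exactly zero at contact
    (``d == r_i + r_k``) and beyond the cutoff ``sigma * r_i``.
    """
    if d <= 0:
        raise InvalidGeometryError(
            "pair force undefined for coincident centres (d <= 0); "
            "separate the cells by a tiny random offset first"
        )
    if params.symmetrise_cutoff:
        cutoff = params.sigma * min(r_i, r_k)
    else:
        cutoff = params.sigma * r_i
    if d >= cutoff:
        return 0.0
    u = d - (r_i + r_k)
    return 2.0 * (math.exp(-2.0 * params.a * u) - math.exp(-params.a * u))


def net_forces(pos: np.ndarray, radius: np.ndarray, params: MechanicsParams) -> np.ndarray:
    """Net force vectors on all cells (vectorised over cutoff neighbour pairs).

    Uses a k-d tree to enumerate pairs within the largest possible cutoff and
    applies the per-cell cutoff mask afterwards; identical to the all-pairs
    sum by construction.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    if n < 2:
        return forces
    tree = cKDTree(pos)
    pairs = tree.query_pairs(params.sigma * float(radius.max()), output_type="ndarray")
    if pairs.shape[0] == 0:
        return forces
    i, k = pairs[:, 0], pairs[:, 1]
    dvec = pos[i] - pos[k]
    d = np.linalg.norm(dvec, axis=1)
    if np.any(d <= _COINCIDENT_TOL):
        raise InvalidGeometryError("coincident cell centres encountered")
    u = d - (radius[i] + radius[k])
    mag = 2.0 * (np.exp(-2.0 * params.a * u) - np.exp(-params.a * u))
    contrib = (params.F0 * mag / d)[:, None] * dvec
    if params.symmetrise_cutoff:
        cut = params.sigma * np.minimum(radius[i], radius[k])
        on_i = on_k = d < cut
    else:
        on_i = d < params.sigma * radius[i]
        on_k = d < params.sigma * radius[k]
    np.add.at(forces, i[on_i], contrib[on_i])
    np.add.at(forces, k[on_k], -contrib[on_k])
    return forces


def net_force(index: int, state: SpheroidState, params: MechanicsParams) -> np.ndarray:
    """Net force on one cell from all others (zero beyond the cutoff)."""
    return net_forces(state.pos, state.radius, params)[index]


# --- fast path: jitted pair kernel over a cached candidate-pair list -------
try:  # numba is an accelerator only; the numpy path is the reference
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _pair_kernel(pairs, pos, radius, F0, a, sigma, symmetrise):
        n = pos.shape[0]
        forces = np.zeros((n, 3))
        min_d = 1e300
        for p in range(pairs.shape[0]):
            i = pairs[p, 0]
            k = pairs[p, 1]
            dx = pos[i, 0] - pos[k, 0]
            dy = pos[i, 1] - pos[k, 1]
            dz = pos[i, 2] - pos[k, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < min_d:
                min_d = d
            if d <= 1e-9:
                continue  # caller resolves coincidence and recomputes
            if symmetrise:
                cut = sigma * min(radius[i], radius[k])
                on_i = on_k = d < cut
            else:
                on_i = d < sigma * radius[i]
                on_k = d < sigma * radius[k]
            if not (on_i or on_k):
                continue
            u = d - (radius[i] + radius[k])
            mag = 2.0 * (math.exp(-2.0 * a * u) - math.exp(-a * u)) * F0 / d
            fx = mag * dx
            fy = mag * dy
            fz = mag * dz
            if on_i:
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
            if on_k:
                forces[k, 0] -= fx
                forces[k, 1] -= fy
                forces[k, 2] -= fz
        return forces, min_d

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    _HAVE_NUMBA = False

#: Verlet margin added to the candidate-pair search radius (model length
#: units); pairs are rebuilt once accumulated drift reaches half of it.
_VERLET_MARGIN = 1.0


def _candidate_pairs(state: SpheroidState, params: MechanicsParams) -> np.ndarray:
    cutoff = params.sigma * max(params.r_star, float(state.radius.max()))
    tree = cKDTree(state.pos)
    pairs = tree.query_pairs(cutoff + _VERLET_MARGIN, output_type="ndarray")
    state._pairs = pairs
    state._pairs_n = state.n_cells
    state._drift = 0.0
    return pairs


def _cached_forces(state: SpheroidState, params: MechanicsParams) -> np.ndarray:
    """Forces via the jitted kernel on (possibly cached) candidate pairs.

    Identical to :func:`net_forces` up to float summation order; candidate
    pairs beyond the cutoff contribute exactly zero.  Coincident centres are
    jittered apart (seeded) and the forces recomputed.
    """
    if not _HAVE_NUMBA:
        _resolve_coincident(state)
        return net_forces(state.pos, state.radius, params)
    for _ in range(3):
        pairs = state._pairs
        if (pairs is None or state._pairs_n != state.n_cells
                or 2.0 * state._drift >= _VERLET_MARGIN):
            pairs = _candidate_pairs(state, params)
        forces, min_d = _pair_kernel(pairs, state.pos, state.radius,
                                     params.F0, params.a, params.sigma,
                                     params.symmetrise_cutoff)
        if min_d > _COINCIDENT_TOL or state.n_cells < 2:
            return forces
        _resolve_coincident(state)
        state.invalidate_cache()
    raise InvalidGeometryError("could not resolve coincident centres")


def grow_step(radius: np.ndarray, params: MechanicsParams, dt: float) -> np.ndarray:
    """Advance radii towards r_star by dt using the exact exponential flow.

    dr/dt = k (r_star - r)  =>  r(t+dt) = r_star - (r_star - r(t)) e^{-k dt}.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    decay = math.exp(-params.k_growth * dt)
    return params.r_star - (params.r_star - np.asarray(radius, dtype=float)) * decay


def maybe_divide(
    cell: Cell,
    params: MechanicsParams,
    rng: np.random.Generator,
    inherit_fn: InheritFn | None = None,
    daughter_id: int | None = None,
) -> tuple[Cell, Cell] | None:
    """Single-cell division trial over one time step.

    Returns None if the cell does not divide; otherwise the updated mother
    (same id and position, reduced radius) and the new daughter.  Total cell
    volume (sum of r^3) is conserved exactly.
    """
    if cell.radius <= 0:
        raise ValueError("cell radius must be positive")
    if cell.radius < params.div_threshold_frac * params.r_star:
        return None
    p_fire = 1.0 - math.exp(-params.div_rate * params.dt)
    if rng.random() >= p_fire:
        return None
    r_new = cell.radius * HALF_CBRT
    direction = _random_unit_vector(rng)
    xi = params.delta_frac * r_new * direction
    if inherit_fn is not None and cell.etype != UNASSIGNED:
        e1, e2 = inherit_fn(cell.etype, rng)
    else:
        e1 = e2 = cell.etype
    mother = Cell(id=cell.id, pos=cell.pos.copy(), radius=r_new, etype=e1,
                  parent_id=cell.parent_id)
    did = cell.id + 1 if daughter_id is None else daughter_id
    daughter = Cell(id=did, pos=cell.pos + xi, radius=r_new, etype=e2,
                    parent_id=cell.id)
    return mother, daughter


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    nrm = np.linalg.norm(v)
    while nrm < 1e-12:  # pragma: no cover - probability ~0
        v = rng.normal(size=3)
        nrm = np.linalg.norm(v)
    return v / nrm


def _resolve_coincident(state: SpheroidState) -> None:
    """Jitter apart any coincident centres (seeded, deterministic)."""
    if state.n_cells < 2:
        return
    tree = cKDTree(state.pos)
    pairs = tree.query_pairs(_COINCIDENT_TOL, output_type="ndarray")
    for i, k in pairs:
        direction = _random_unit_vector(state.rng)
        eps = 1e-6 * max(float(state.radius[i]), 1e-6)
        state.pos[k] = state.pos[k] + eps * direction


def step(
    state: SpheroidState,
    params: MechanicsParams,
    inherit_fn: InheritFn | None = None,
    max_divisions: int | None = None,
    mechanics_only: bool = False,
) -> SpheroidState:
    """One explicit time step: forces -> displacement -> growth -> divisions.

    Forces are evaluated on the pre-step configuration and all cells are
    displaced simultaneously.  Division trials run after growth, processed in
    cell-id order for determinism; ``max_divisions`` caps the number of
    divisions executed this step (used to land exactly on a target count).
    Mutates and returns ``state``.
    """
    forces = _cached_forces(state, params)
    disp = params.dt * forces
    max_disp = float(np.max(np.sqrt((disp**2).sum(axis=1)))) if state.n_cells else 0.0
    if max_disp > params.r_star:
        raise StepInstabilityError(
            f"per-step displacement {max_disp:.3g} exceeds r_star={params.r_star}; "
            "reduce dt or relax the configuration first"
        )
    state.pos = state.pos + disp
    state._drift += max_disp
    if not mechanics_only:
        state.radius = grow_step(state.radius, params, params.dt)
        _division_sweep(state, params, inherit_fn, max_divisions)
    state.time += params.dt
    return state


def _division_sweep(
    state: SpheroidState,
    params: MechanicsParams,
    inherit_fn: InheritFn | None,
    max_divisions: int | None,
) -> None:
    n = state.n_cells
    eligible = state.radius >= params.div_threshold_frac * params.r_star
    p_fire = 1.0 - math.exp(-params.div_rate * params.dt)
    fired = state.rng.random(n) < p_fire
    idxs = np.flatnonzero(eligible & fired)  # ascending index == ascending id
    if max_divisions is not None:
        idxs = idxs[:max_divisions]
    if idxs.size == 0:
        return
    new_pos, new_rad, new_ety, new_ids, new_par = [], [], [], [], []
    for idx in idxs:
        r_new = float(state.radius[idx]) * HALF_CBRT
        direction = _random_unit_vector(state.rng)
        xi = params.delta_frac * r_new * direction
        mother_type = int(state.etype[idx])
        if inherit_fn is not None and mother_type != UNASSIGNED:
            e1, e2 = inherit_fn(mother_type, state.rng)
        else:
            e1 = e2 = mother_type
        state.radius[idx] = r_new
        state.etype[idx] = e1
        did = state.next_id
        state.next_id += 1
        new_pos.append(state.pos[idx] + xi)
        new_rad.append(r_new)
        new_ety.append(e2)
        new_ids.append(did)
        new_par.append(int(state.ids[idx]))
        state.event_log.append((state.time + params.dt, "division",
                                (int(state.ids[idx]), did)))
    state.pos = np.vstack([state.pos, np.array(new_pos)])
    state.radius = np.concatenate([state.radius, np.array(new_rad)])
    state.etype = np.concatenate([state.etype, np.array(new_ety, dtype=np.int8)])
    state.ids = np.concatenate([state.ids, np.array(new_ids, dtype=np.int64)])
    state.parent = np.concatenate([state.parent, np.array(new_par, dtype=np.int64)])


def relax(
    state: SpheroidState,
    params: MechanicsParams,
    n_steps: int,
    max_disp_frac: float = 0.25,
) -> SpheroidState:
    """Force-only relaxation: no growth, no division, capped displacement.

    If the raw Euler displacement of any cell would exceed
    ``max_disp_frac * r_star`` the whole step is rescaled, which keeps the
    relaxation stable even for heavily overlapping initial packings.
    """
    cap = max_disp_frac * params.r_star
    for _ in range(n_steps):
        forces = _cached_forces(state, params)
        disp = params.dt * forces
        max_disp = float(np.max(np.sqrt((disp**2).sum(axis=1))))
        if max_disp > cap:
            disp *= cap / max_disp
            max_disp = cap
        state.pos = state.pos + disp
        state._drift += max_disp
        state.time += params.dt
    return state


def init_spheroid(
    n0: int,
    params: MechanicsParams,
    seed: int | np.random.Generator = 0,
    relax_steps: int = 200,
    packing: float = 0.4,
) -> SpheroidState:
    """Build a relaxed spheroid of ``n0`` undifferentiated cells.

    Positions are sampled uniformly in a ball sized for near-contact density
    (``packing`` is the target sphere-volume fraction), radii uniformly in
    ``[2^{-1/3}, 1] * r_star`` to desynchronise the division clock, and the
    packing is relaxed by force-only steps before the growth clock starts.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_lo, r_hi = HALF_CBRT * params.r_star, params.r_star
    radius = rng.uniform(r_lo, r_hi, size=n0)
    if n0 == 1:
        pos = np.zeros((1, 3))
    else:
        mean_r3 = float(np.mean(radius**3))
        ball_r = (n0 * mean_r3 / packing) ** (1.0 / 3.0)
        u = rng.normal(size=(n0, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = u * (ball_r * rng.random(n0) ** (1.0 / 3.0))[:, None]
    state = SpheroidState(
        pos=pos,
        radius=radius,
        etype=np.full(n0, UNASSIGNED, dtype=np.int8),
        ids=np.arange(n0, dtype=np.int64),
        parent=np.full(n0, -1, dtype=np.int64),
        time=0.0,
        rng=rng,
        next_id=n0,
    )
    if n0 > 1 and relax_steps > 0:
        relax(state, params, relax_steps)
        state.time = 0.0
    return state


def run_until_count(
    state: SpheroidState,
    params: MechanicsParams,
    target_count: int,
    inherit_fn: InheritFn | None = None,
    max_steps: int = 500_000,
    stall_steps: int = 50_000,
) -> SpheroidState:
    """Step until the cell count first equals ``target_count`` (no overshoot).

    Divisions within a step are capped at the remaining deficit, so the
    returned snapshot has exactly the requested count.
    """
    if target_count < state.n_cells:
        raise ValueError(
            f"target_count {target_count} below current count {state.n_cells}"
        )
    steps = 0
    last_change = 0
    while state.n_cells < target_count:
        before = state.n_cells
        step(state, params, inherit_fn=inherit_fn,
             max_divisions=target_count - state.n_cells)
        steps += 1
        if state.n_cells != before:
            last_change = steps
        if steps >= max_steps:
            raise NonProgressError(f"no convergence within {max_steps} steps")
        if steps - last_change >= stall_steps:
            raise NonProgressError(
                f"no division within {stall_steps} consecutive steps"
            )
    return state


def max_overlap_fraction(pos: np.ndarray, radius: np.ndarray) -> float:
    """Largest pairwise overlap (r_i + r_k - d) / (r_i + r_k); <= 0 means none."""
    n = pos.shape[0]
    if n < 2:
        return 0.0
    tree = cKDTree(pos)
    pairs = tree.query_pairs(2.0 * float(radius.max()), output_type="ndarray")
    if pairs.shape[0] == 0:
        return 0.0
    i, k = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(pos[i] - pos[k], axis=1)
    s = radius[i] + radius[k]
    return float(np.max((s - d) / s))
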