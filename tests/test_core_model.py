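"""Mechanics unit tests: forces, growth, division, stepping, initialisation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icmsim import MechanicsParams
from icmsim.core_model import (HALF_CBRT, SpheroidState, grow_step,
                               init_spheroid, max_overlap_fraction,
                               maybe_divide, net_force, net_forces,
                               pair_force_magnitude, relax, run_until_count,
                               step)
from icmsim.errors import (InvalidGeometryError, NonProgressError,
                           StepInstabilityError)
from icmsim.types import UNASSIGNED, Cell

PARAMS = MechanicsParams()

# closed-form value of 2*(e^{1.2} - e^{0.6}) for r_i=r_k=1, d=1, a=0.6
FORCE_AT_D1 = 2.9959962446920766


def _state(pos, radius, seed=0):
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    return SpheroidState(
        pos=pos, radius=np.asarray(radius, dtype=float),
        etype=np.full(n, UNASSIGNED, dtype=np.int8),
        ids=np.arange(n, dtype=np.int64),
        parent=np.full(n, -1, dtype=np.int64),
        time=0.0, rng=np.random.default_rng(seed), next_id=n)


class TestPairForce:
    @pytest.mark.parametrize("r_i,r_k,d,expected", [
        (1.0, 1.0, 2.0, 0.0),            # contact: no interaction
        (1.0, 1.0, 4.5, 0.0),            # beyond cutoff sigma*r_i = 4
        (1.0, 1.0, 4.0, 0.0),            # cutoff boundary is exclusive
        (1.0, 1.0, 1.0, FORCE_AT_D1),    # compressed pair, closed form
    ])
    def test_reference_values(self, r_i, r_k, d, expected):
        assert pair_force_magnitude(r_i, r_k, d, PARAMS) == pytest.approx(
            expected, abs=1e-12)

    def test_coincident_centres_rejected(self):
        with pytest.raises(InvalidGeometryError):
            pair_force_magnitude(1.0, 1.0, 0.0, PARAMS)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(r=st.floats(0.6, 1.0), frac=st.floats(0.05, 2.5))
    def test_sign_structure(self, r, frac):
        """Repulsive below contact, attractive up to the cutoff, zero beyond."""
        d = frac * 2 * r
        f = pair_force_magnitude(r, r, d, PARAMS)
        if d < 2 * r:
            assert f > 0
        elif d < PARAMS.sigma * r:
            assert f < 0 or math.isclose(d, 2 * r)
        else:
            assert f == 0.0

    def test_cutoff_asymmetry_for_unequal_radii(self):
        """The cutoff depends on the focal cell radius only: in the band
        between sigma*r_i and sigma*r_k the smaller cell feels nothing
        while the larger one still does."""
        r_small, r_large, d = 0.8, 1.0, 3.5  # 3.2 < d < 4.0
        assert pair_force_magnitude(r_small, r_large, d, PARAMS) == 0.0
        assert pair_force_magnitude(r_large, r_small, d, PARAMS) != 0.0
        sym = MechanicsParams(symmetrise_cutoff=True)
        assert pair_force_magnitude(r_small, r_large, d, sym) == 0.0
        assert pair_force_magnitude(r_large, r_small, d, sym) == 0.0


class TestNetForce:
    def test_single_cell_zero(self):
        s = _state([[0, 0, 0]], [1.0])
        assert np.allclose(net_force(0, s, PARAMS), 0.0)

    def test_contact_pair_zero(self):
        s = _state([[0, 0, 0], [2, 0, 0]], [1.0, 1.0])
        assert np.allclose(net_forces(s.pos, s.radius, PARAMS), 0.0,
                           atol=1e-12)

    def test_compressed_pair_repels_along_axis(self):
        s = _state([[0, 0, 0], [1, 0, 0]], [1.0, 1.0])
        f = net_forces(s.pos, s.radius, PARAMS)
        assert f[0] == pytest.approx([-FORCE_AT_D1, 0, 0], abs=1e-10)
        assert f[1] == pytest.approx([FORCE_AT_D1, 0, 0], abs=1e-10)

    def test_beyond_cutoff_contributes_zero(self):
        s = _state([[0, 0, 0], [10, 0, 0]], [1.0, 1.0])
        assert np.all(net_forces(s.pos, s.radius, PARAMS) == 0.0)

    def test_equal_radii_newton_third_law(self):
        rng = np.random.default_rng(3)
        pos = rng.random((12, 3)) * 4
        f = net_forces(pos, np.ones(12), PARAMS)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)


class TestGrowth:
    def test_fixed_point(self):
        r = grow_step(np.array([PARAMS.r_star]), PARAMS, 0.5)
        assert r[0] == pytest.approx(PARAMS.r_star, abs=1e-15)

    def test_matches_closed_form(self):
        """r(t) = r_star - (r_star - r0) e^{-kt}; stepping must track it to
        1e-4 over t in [0, 5] at the default dt."""
        r0, dt = 0.5, PARAMS.dt
        r = np.array([r0])
        t = 0.0
        while t < 5.0:
            r = grow_step(r, PARAMS, dt)
            t += dt
            closed = PARAMS.r_star - (PARAMS.r_star - r0) * math.exp(-t)
            assert abs(r[0] - closed) < 1e-4

    def test_half_life_value(self):
        r = grow_step(np.array([0.5]), PARAMS, math.log(2))
        assert r[0] == pytest.approx(0.75, abs=1e-12)

    def test_monotone_and_bounded(self):
        r = np.array([0.6])
        for _ in range(1000):
            r_next = grow_step(r, PARAMS, PARAMS.dt)
            assert r_next[0] >= r[0]
            assert r_next[0] <= PARAMS.r_star
            r = r_next


class TestDivision:
    def test_volume_conserved_and_radius_factor(self):
        cell = Cell(id=0, pos=np.zeros(3), radius=1.0, etype=0)
        fast = MechanicsParams(div_rate=1e6)  # hazard ~1 per step
        got = maybe_divide(cell, fast, np.random.default_rng(0))
        assert got is not None
        mother, daughter = got
        assert mother.radius == pytest.approx(HALF_CBRT, abs=1e-12)
        assert daughter.radius == mother.radius
        assert mother.radius**3 + daughter.radius**3 == pytest.approx(
            1.0, abs=1e-12)
        assert np.allclose(mother.pos, cell.pos)
        offset = np.linalg.norm(daughter.pos - mother.pos)
        assert offset == pytest.approx(fast.delta_frac * daughter.radius,
                                       rel=1e-9)
        assert daughter.parent_id == mother.id

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(r=st.floats(0.5, 1.0))
    def test_volume_identity_any_radius(self, r):
        assert 2 * (r * HALF_CBRT) ** 3 == pytest.approx(r**3, rel=1e-12)

    def test_below_threshold_never_divides(self):
        cell = Cell(id=0, pos=np.zeros(3), radius=0.5, etype=0)
        fast = MechanicsParams(div_rate=1e6)
        rng = np.random.default_rng(0)
        assert all(maybe_divide(cell, fast, rng) is None for _ in range(200))

    def test_step_conserves_volume_at_division(self):
        """With negligible growth, total r^3 is invariant through a step in
        which divisions fire."""
        params = MechanicsParams(k_growth=1e-9, div_rate=1e6)
        state = init_spheroid(30, params, seed=5, relax_steps=20)
        state.radius[:] = 0.99  # all eligible
        before = float(np.sum(state.radius**3))
        step(state, params)
        assert state.n_cells > 30
        assert float(np.sum(state.radius**3)) == pytest.approx(
            before, rel=1e-9)


class TestStep:
    def test_contact_pair_only_clock_advances(self):
        s = _state([[0, 0, 0], [2, 0, 0]], [1.0, 1.0])
        step(s, PARAMS, max_divisions=0)
        assert np.allclose(s.pos, [[0, 0, 0], [2, 0, 0]], atol=1e-12)
        assert np.allclose(s.radius, 1.0)
        assert s.time == pytest.approx(PARAMS.dt)

    def test_compressed_pair_separates(self):
        s = _state([[0, 0, 0], [1.0, 0, 0]], [1.0, 1.0])
        step(s, PARAMS, max_divisions=0)
        assert np.linalg.norm(s.pos[1] - s.pos[0]) > 1.0

    def test_three_cell_chain_relaxes_to_static_equilibrium(self):
        """A symmetric 3-cell chain settles where the repulsion of the inner
        pair balances the attraction of the outer pair; the equilibrium
        spacing solves F(x) + F(2x) = 0 (computed independently)."""
        from scipy.optimize import brentq

        def balance(x):
            return (pair_force_magnitude(1, 1, x, PARAMS)
                    + pair_force_magnitude(1, 1, 2 * x, PARAMS))

        # bracket excludes the trivial root at contact+cutoff (x=2, 2x=4)
        x_eq = brentq(balance, 1.5, 1.9)
        s = _state([[-1.8, 0, 0], [0, 0, 0], [1.8, 0, 0]], [1.0] * 3)
        for _ in range(4000):
            step(s, PARAMS, mechanics_only=True)
        d01 = np.linalg.norm(s.pos[1] - s.pos[0])
        d12 = np.linalg.norm(s.pos[2] - s.pos[1])
        assert d01 == pytest.approx(x_eq, abs=5e-3)
        assert d12 == pytest.approx(x_eq, abs=5e-3)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        pos = rng.random((20, 3)) * 5
        sa = _state(pos, np.full(20, 0.9))
        sb = _state(pos + np.array([100.0, -50.0, 3.0]), np.full(20, 0.9))
        for _ in range(10):
            step(sa, PARAMS, mechanics_only=True)
            step(sb, PARAMS, mechanics_only=True)
        assert np.allclose(sb.pos - np.array([100.0, -50.0, 3.0]), sa.pos,
                           atol=1e-8)

    def test_instability_guard(self):
        s = _state([[0, 0, 0], [0.05, 0, 0]], [1.0, 1.0])
        big_dt = MechanicsParams(dt=10.0)
        with pytest.raises(StepInstabilityError):
            step(s, big_dt)


class TestInitAndRun:
    def test_single_cell_at_origin(self):
        s = init_spheroid(1, PARAMS, seed=0)
        assert s.n_cells == 1
        assert np.allclose(s.pos, 0.0)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            init_spheroid(0, PARAMS)

    def test_initial_population_properties(self):
        s = init_spheroid(200, PARAMS, seed=4)
        assert s.n_cells == 200
        assert np.all(s.etype == UNASSIGNED)
        assert np.all(s.radius >= HALF_CBRT * PARAMS.r_star - 1e-12)
        assert np.all(s.radius <= PARAMS.r_star + 1e-12)
        assert len(np.unique(s.ids)) == 200

    def test_relaxation_reaches_near_equilibrium(self):
        """Relaxation must bring the packing close to force balance.  The
        long-range adhesive tail of the potential compresses the packing, so
        residual pairwise overlap is substantial at equilibrium; the check
        is on force residuals and on overlap not exceeding the equilibrium
        scale."""
        s = init_spheroid(100, PARAMS, seed=4, relax_steps=0)
        relax(s, PARAMS, 1000)
        f1 = float(np.max(np.linalg.norm(
            net_forces(s.pos, s.radius, PARAMS), axis=1)))
        assert f1 < 1.0
        assert max_overlap_fraction(s.pos, s.radius) < 0.8

    def test_run_until_count_exact(self):
        params = MechanicsParams()
        s = init_spheroid(40, params, seed=6, relax_steps=50)
        run_until_count(s, params, 40)  # immediate return
        assert s.n_cells == 40 and s.time == 0.0
        run_until_count(s, params, 71)
        assert s.n_cells == 71

    def test_non_progress_guard(self):
        no_div = MechanicsParams(div_rate=1e-12)
        s = init_spheroid(5, no_div, seed=0, relax_steps=10)
        with pytest.raises(NonProgressError):
            run_until_count(s, no_div, 10, stall_steps=50, max_steps=100)

    def test_determinism_bit_identical(self):
        def run(seed):
            params = MechanicsParams()
            s = init_spheroid(30, params, seed=seed, relax_steps=50)
            run_until_count(s, params, 50)
            return s

        a, b = run(11), run(11)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.radius, b.radius)
        assert a.event_log == b.event_log
        c = run(12)
        assert not np.array_equal(a.pos, c.pos)
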