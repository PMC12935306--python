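"""Simulator invariants: positivity, capacity, conservation, symmetry,
logistic limit, monotone dependence on the growth-rate ratio, and grid
convergence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quorumcomp.biofilm import (BiofilmState, FounderLayout, FounderSpot,
                                SimGrid, SimulationConfig, StabilityError,
                                StrainParams, initial_state,
                                make_founder_layout, mirrored_layout,
                                outcome_summary, simulate,
                                stability_dt_max, step,
                                sweep_relative_growth)


def uniform_grid(n=24, h=0.5):
    return SimGrid(n, n, h, np.ones((n, n), bool))


class TestStep:
    def test_dt_above_stability_bound_is_rejected(self, equal_strains):
        g = uniform_grid()
        bound = stability_dt_max(g, equal_strains)
        state = BiofilmState(np.zeros((24, 24)), np.zeros((24, 24)))
        with pytest.raises(StabilityError, match="stability bound"):
            step(state, equal_strains, g, 1.01 * bound)

    def test_uniform_state_increment_is_pure_logistic(self, equal_strains):
        # no gradients => diffusion contributes nothing anywhere
        g = uniform_grid()
        dt = 0.4 * stability_dt_max(g, equal_strains)
        state = BiofilmState(np.full((24, 24), 0.2), np.zeros((24, 24)))
        out = step(state, equal_strains, g, dt)
        expected = 0.2 + equal_strains[0].r * 0.2 * 0.8 * dt
        assert np.abs(out.B1 - expected).max() == 0.0
        assert out.B2.max() == 0.0

    def test_zero_growth_conserves_mass_per_step(self):
        g = uniform_grid()
        strains = (StrainParams("B1", 1e-300, 1.0), StrainParams("B2", 1e-300, 1.0))
        rng = np.random.default_rng(5)
        state = BiofilmState(rng.uniform(0, 0.5, (24, 24)),
                             rng.uniform(0, 0.5, (24, 24)))
        dt = 0.5 * stability_dt_max(g, strains)
        m1, m2 = state.B1.sum(), state.B2.sum()
        for _ in range(40):
            state = step(state, strains, g, dt)
            assert abs(state.B1.sum() - m1) / m1 < 1e-10
            assert abs(state.B2.sum() - m2) / m2 < 1e-10

    def test_single_cell_no_motility_matches_logistic_closed_form(self):
        g = SimGrid(1, 1, 1.0, np.ones((1, 1), bool))
        strains = (StrainParams("B1", 1.0, 0.0), StrainParams("B2", 1.0, 0.0))
        dt, t_end, b0 = 1e-3, 5.0, 0.01
        state = BiofilmState(np.array([[b0]]), np.zeros((1, 1)))
        for _ in range(int(t_end / dt)):
            state = step(state, strains, g, dt)
        exact = b0 * math.exp(t_end) / (1 + b0 * (math.exp(t_end) - 1))
        assert abs(state.B1[0, 0] - exact) / exact < 1e-3

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), r1=st.floats(0.2, 2.0),
           r2=st.floats(0.2, 2.0), fill=st.floats(0.05, 0.95))
    def test_positivity_and_capacity_hold_after_every_step(self, seed, r1, r2, fill):
        g = SimGrid.disc(radius=4.0, nx=20)
        strains = (StrainParams("B1", r1, 1.0), StrainParams("B2", r2, 1.0))
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (20, 20))
        b = rng.uniform(0, 1, (20, 20))
        scale = fill / np.maximum(a + b, 1e-12).max()
        state = BiofilmState(np.where(g.mask, a * scale, 0),
                             np.where(g.mask, b * scale, 0))
        dt = 0.5 * stability_dt_max(g, strains)
        for _ in range(25):
            state = step(state, strains, g, dt)
            assert state.B1.min() >= 0 and state.B2.min() >= 0
            assert (state.B1 + state.B2).max() <= 1 + 1e-9

    def test_strain_relabelling_swaps_outputs_exactly(self):
        g = SimGrid.disc(radius=4.0, nx=24)
        s1 = StrainParams("B1", 1.0, 1.0)
        s2 = StrainParams("B2", 1.4, 1.0)
        rng = np.random.default_rng(2)
        a = np.where(g.mask, rng.uniform(0, 0.4, (24, 24)), 0)
        b = np.where(g.mask, rng.uniform(0, 0.4, (24, 24)), 0)
        dt = 0.5 * stability_dt_max(g, (s1, s2))
        x = step(BiofilmState(a, b), (s1, s2), g, dt)
        y = step(BiofilmState(b, a), (s2, s1), g, dt)
        assert np.array_equal(x.B1, y.B2) and np.array_equal(x.B2, y.B1)


class TestLayouts:
    def test_same_seed_gives_identical_layout(self):
        a = make_founder_layout(10, 3.0, 0.5, 0.5, seed=3)
        b = make_founder_layout(10, 3.0, 0.5, 0.5, seed=3)
        assert a.spots == b.spots

    def test_spots_lie_within_inoculum_disc(self):
        lay = make_founder_layout(50, 4.0, 0.3, 0.5, seed=1)
        for s in lay.spots:
            assert math.hypot(s.x, s.y) <= 4.0 + 1e-12

    def test_overfull_inoculum_is_rejected(self, small_grid):
        with pytest.raises(ValueError, match="exceeds the domain"):
            make_founder_layout(5, 100.0, 0.5, 0.5, seed=1, grid=small_grid)

    def test_empty_layout_leaves_domain_empty(self, small_grid, equal_strains):
        cfg = SimulationConfig(small_grid, equal_strains,
                               FounderLayout([], 0), t_end=1.0)
        res = simulate(cfg)
        assert res.state.B1.max() == 0 and res.state.B2.max() == 0
        assert math.isnan(res.outcome.f1)

    def test_overlapping_spots_capped_proportionally(self, small_grid):
        lay = FounderLayout([FounderSpot(0, 0, 1.0, 0, 0.9),
                             FounderSpot(0, 0, 1.0, 1, 0.9)], 0)
        state = initial_state(small_grid, lay)
        tot = state.B1 + state.B2
        assert tot.max() <= 1 + 1e-12
        np.testing.assert_allclose(state.B1[tot > 0], state.B2[tot > 0])


class TestSimulate:
    def test_mirrored_equal_rate_outcome_is_exactly_half(self, equal_strains):
        g = SimGrid.disc(radius=8.0, nx=64)
        lay = mirrored_layout(8, 2.5, 0.6, 0.5, seed=13)
        res = simulate(SimulationConfig(g, equal_strains, lay, t_end=8.0))
        assert res.outcome.f1 == 0.5 and res.outcome.f2 == 0.5

    def test_absent_strain_stays_identically_zero(self, small_grid, equal_strains):
        spots = [FounderSpot(0.0, 0.0, 1.5, 0, 0.5)]
        res = simulate(SimulationConfig(small_grid, equal_strains,
                                        FounderLayout(spots, 0), t_end=5.0))
        assert res.state.B2.max() == 0.0
        assert res.outcome.f1 == 1.0

    def test_growth_advantage_dominates(self, small_grid):
        strains = (StrainParams("B1", 1.0, 1.0), StrainParams("B2", 1.3, 1.0))
        lay = mirrored_layout(6, 2.5, 0.6, 0.5, seed=4)
        res = simulate(SimulationConfig(small_grid, strains, lay, t_end=10.0))
        assert res.outcome.f2 > 0.5

    def test_sweep_is_sorted_and_strictly_increasing(self, small_grid, equal_strains):
        lay = make_founder_layout(8, 2.5, 0.5, 0.5, seed=6, grid=small_grid)
        base = SimulationConfig(small_grid, equal_strains, lay, t_end=10.0)
        tab = sweep_relative_growth(base, [1.2, 0.8, 1.0, 1.3])
        assert list(tab["rho"]) == [0.8, 1.0, 1.2, 1.3]
        assert tab["f2_final"].is_monotonic_increasing
        assert tab["f2_final"].diff().dropna().gt(0).all()

    def test_grid_convergence_of_final_fraction(self):
        strains = (StrainParams("B1", 1.0, 1.0), StrainParams("B2", 1.2, 1.0))
        lay = mirrored_layout(6, 2.5, 0.8, 0.5, seed=9)
        f2 = []
        for nx in (48, 96):
            g = SimGrid.disc(radius=8.0, nx=nx)
            res = simulate(SimulationConfig(g, strains, lay, t_end=8.0))
            f2.append(res.outcome.f2)
        assert abs(f2[1] - f2[0]) < 0.01

    def test_snapshots_are_recorded(self, small_grid, equal_strains):
        lay = mirrored_layout(4, 2.0, 0.6, 0.5, seed=2)
        res = simulate(SimulationConfig(small_grid, equal_strains, lay,
                                        t_end=2.0, snapshot_every=1.0))
        assert len(res.snapshots) >= 3
        assert res.snapshots[0].t == 0.0


class TestOutcome:
    def test_fractions_sum_to_one_and_percent_matches(self, small_grid):
        rng = np.random.default_rng(0)
        B1 = np.where(small_grid.mask, rng.uniform(0, 0.4, small_grid.mask.shape), 0)
        B2 = np.where(small_grid.mask, rng.uniform(0, 0.4, small_grid.mask.shape), 0)
        o = outcome_summary(BiofilmState(B1, B2), small_grid)
        assert o.f1 + o.f2 == pytest.approx(1.0, abs=1e-12)
        assert o.percent_challenger_remaining == pytest.approx(100 * o.f1)
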