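"""Unit and property tests for the cell-array growth/division engine."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from bullseye import (
    Fate, InitialState, ModelParams, Tissue,
    divide_cell, division_propensity, growth_increment,
    simulate, simulate_exact, step,
)
from bullseye.errors import InvalidStateError, CellNotFoundError, NoProgressError


class TestGrowthRule:
    def test_zero_at_maximum_length(self, wt_params):
        assert growth_increment(wt_params.l_max, Fate.DISTAL, wt_params, 1.0) == 0.0
        assert growth_increment(wt_params.l_max, Fate.PROXIMAL, wt_params, 1.0) == 0.0

    def test_logistic_midpoint_value(self, wt_params):
        # l = l_max/2: increment = r_g * 10 * (1 - 0.5) * dt
        assert growth_increment(10.0, Fate.DISTAL, wt_params, 1.0) == pytest.approx(4.55)

    def test_small_length_exponential_limit(self, wt_params):
        eps = 1e-9
        rate = growth_increment(eps, Fate.DISTAL, wt_params, 1.0) / eps
        assert rate == pytest.approx(wt_params.r_g_distal, rel=1e-6)

    def test_proximal_ratio_scales_rate(self):
        p = ModelParams(r_g_ratio=1.5)
        inc_d = growth_increment(1.0, Fate.DISTAL, p, 1.0)
        inc_p = growth_increment(1.0, Fate.PROXIMAL, p, 1.0)
        assert inc_p == pytest.approx(1.5 * inc_d)

    def test_rejects_nonpositive_length(self, wt_params):
        with pytest.raises(InvalidStateError):
            growth_increment(0.0, Fate.DISTAL, wt_params)
        with pytest.raises(InvalidStateError):
            growth_increment(-1.0, Fate.DISTAL, wt_params)

    @given(l=st.floats(0.01, 19.99), dt=st.floats(0.001, 0.05))
    @settings(deadline=None, max_examples=50)
    def test_never_overshoots_lmax(self, l, dt):
        p = ModelParams()
        assert l + growth_increment(l, Fate.PROXIMAL, p, dt) <= p.l_max + 1e-12


class TestDivisionRule:
    def test_base_rate_at_zero_length(self, wt_params):
        assert division_propensity(Fate.DISTAL, 0.0, wt_params) == pytest.approx(1.1)

    def test_decay_at_L0(self, wt_params):
        # L = L0(0) = 30: rate = 1.1/e
        got = division_propensity(Fate.DISTAL, 30.0, wt_params)
        assert got == pytest.approx(1.1 / np.e, rel=1e-12)
        assert got == pytest.approx(0.4046673852885866)

    def test_divisions_effectively_stop_at_target_length(self, wt_params):
        got = division_propensity(Fate.DISTAL, 300.0, wt_params)
        assert got == pytest.approx(1.1 * np.exp(-10), rel=1e-12)
        assert got < 1e-4

    def test_proximal_uses_larger_L0(self, wt_params):
        # L0(1) = 30/0.6 = 50: proximal divisions decay later
        prox = division_propensity(Fate.PROXIMAL, 100.0, wt_params)
        dist = division_propensity(Fate.DISTAL, 100.0, wt_params)
        assert prox == pytest.approx(1.1 * np.exp(-2.0))
        assert prox > dist

    @given(L1=st.floats(0, 500), L2=st.floats(0, 500))
    @settings(deadline=None, max_examples=50)
    def test_strictly_decreasing_in_L(self, L1, L2):
        p = ModelParams()
        if L1 > L2:
            L1, L2 = L2, L1
        d1 = division_propensity(Fate.DISTAL, L1, p)
        d2 = division_propensity(Fate.DISTAL, L2, p)
        assert d1 >= d2
        if L2 - L1 > 1e-6:
            assert d1 > d2


class TestDivideCell:
    def test_single_cell_splits_in_half(self):
        t = Tissue([1], [0], [0.2])
        t2 = divide_cell(t, 1)
        assert t2.n_cells == 2
        assert np.allclose(t2.lengths, [0.1, 0.1])
        assert t2.total_length == pytest.approx(0.2)

    def test_fresh_id_and_neighbor_insertion(self):
        t = Tissue.from_initial(InitialState())
        t2 = divide_cell(t, 7)
        assert t2.n_cells == 22
        assert 22 in t2.cids
        # daughter sits immediately right of the mother, same fate
        i = int(np.flatnonzero(t2.cids == 7)[0])
        assert t2.cids[i + 1] == 22
        assert t2.fates[i + 1] == t2.fates[i] == Fate.PROXIMAL
        assert (t2.fates == Fate.PROXIMAL).sum() == 8
        t2.validate()

    def test_unknown_cid_raises(self):
        t = Tissue.from_initial(InitialState())
        with pytest.raises(CellNotFoundError):
            divide_cell(t, 99)

    @given(st.integers(1, 21))
    @settings(deadline=None, max_examples=21)
    def test_division_conserves_total_and_regional_lengths(self, cid):
        t = Tissue.from_initial(InitialState())
        before = t.counts_and_lengths()
        after = divide_cell(t, cid).counts_and_lengths()
        assert after[2] == pytest.approx(before[2], abs=1e-15)  # tl0
        assert after[3] == pytest.approx(before[3], abs=1e-15)  # tl1
        # boundary observable unchanged at the instant of division
        assert divide_cell(t, cid).boundary_position == pytest.approx(
            t.boundary_position, abs=1e-15)


class TestStep:
    def test_determinism_same_seed(self, wt_params):
        t1 = simulate(wt_params, seed=7)
        t2 = simulate(wt_params, seed=7)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.tl0, t2.tl0)
        assert np.array_equal(t1.nc1, t2.nc1)

    def test_pure_growth_approaches_lmax(self):
        p = ModelParams(r_d_distal=0.0, L_max=400.0)
        t = Tissue(np.arange(1, 22), [1]*7 + [0]*14, np.full(21, 0.1))
        rng = np.random.default_rng(0)
        for _ in range(3000):
            step(t, p, rng)
        assert t.n_cells == 21  # no divisions ever
        assert np.all(t.lengths > 0.99 * p.l_max)

    def test_zero_growth_never_terminates(self):
        p = ModelParams(r_g_distal=0.0)
        with pytest.raises(NoProgressError):
            simulate(p, max_steps=300)

    def test_contiguity_preserved_along_run(self, wt_params):
        traj = simulate(wt_params, seed=11, record_cells=True)
        for snap in traj.snapshots[:: max(1, len(traj.snapshots) // 20)]:
            snap.validate(l_max=wt_params.l_max)

    def test_total_length_strictly_increases(self, wt_params):
        traj = simulate(wt_params, seed=2)
        assert np.all(np.diff(traj.total_length) > 0)


class TestSimulate:
    def test_initial_state_arithmetic(self, default_init):
        t = Tissue.from_initial(default_init)
        assert t.total_length == pytest.approx(2.1)
        assert t.boundary_position == pytest.approx(1.0 / 3.0)

    def test_terminates_at_target_length(self, wt_params):
        for seed in range(3):
            traj = simulate(wt_params, seed=seed)
            assert traj.total_length[-1] >= wt_params.L_max

    def test_small_dt_convergence_of_mean_boundary(self, wt_params):
        n = 30
        m1 = np.mean([simulate(wt_params, seed=s).final_boundary for s in range(n)])
        half = replace(wt_params, dt=wt_params.dt / 2)
        m2 = np.mean([simulate(half, seed=s).final_boundary for s in range(n)])
        assert abs(m1 - m2) < 0.01

    def test_exact_engine_agrees_with_hybrid(self, wt_params):
        # event-driven thinning engine: same model, same ensemble behaviour
        n = 25
        mh = np.mean([simulate(wt_params, seed=s).final_boundary for s in range(n)])
        me = np.mean([simulate_exact(wt_params, seed=s).final_boundary for s in range(n)])
        assert abs(mh - me) < 0.03
        te = simulate_exact(wt_params, seed=0)
        assert te.total_length[-1] >= wt_params.L_max - 1e-6


class TestBranchingOracle:
    def test_division_counts_match_galton_watson_law(self):
        """With growth off, L is frozen and each cell divides per step with
        constant probability p: the cell count after k steps is a
        Galton-Watson process with offspring 1 or 2. Compare the simulated
        ensemble mean and variance with the closed-form GW moments."""
        p_model = ModelParams(r_g_distal=0.0, r_d_distal=1.1, dt=0.05,
                              L0_distal=1e7)
        n0, k, n_runs = 3, 20, 2000
        p = -np.expm1(-1.1 * 0.05)  # per-step division probability
        counts = np.empty(n_runs)
        for r in range(n_runs):
            t = Tissue(np.arange(1, n0 + 1), [0] * n0, np.full(n0, 0.1))
            rng = np.random.default_rng(1000 + r)
            for _ in range(k):
                step(t, p_model, rng)
            counts[r] = t.n_cells
        m0, s0sq = 1 + p, p * (1 - p)
        mean_th = n0 * m0**k
        var_th = n0 * s0sq * m0 ** (k - 1) * (m0**k - 1) / (m0 - 1)
        assert counts.mean() == pytest.approx(mean_th, rel=0.02)
        assert counts.var(ddof=1) == pytest.approx(var_th, rel=0.15)


class TestParamsValidation:
    def test_table_defaults(self, wt_params):
        assert wt_params.r_d(Fate.DISTAL) == 1.1
        assert wt_params.r_g(Fate.DISTAL) == 0.91
        assert wt_params.L0(Fate.DISTAL) == pytest.approx(0.1 * wt_params.L_max)
        assert wt_params.L0(Fate.PROXIMAL) == pytest.approx(50.0)

    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0}, {"dt": 0.2}, {"l_max": -1.0}, {"r_g_ratio": 0.0},
        {"r_g_distal": -0.1},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_invalid_initial_state_rejected(self):
        with pytest.raises(ValueError):
            InitialState(n_cells=5, n_proximal=5)

    def test_params_roundtrip_from_yaml(self, tmp_path):
        import yaml
        path = tmp_path / "p.yaml"
        path.write_text(yaml.safe_dump(ModelParams(r_g_ratio=1.3).to_dict()))
        assert ModelParams.from_file(path).r_g_ratio == 1.3
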