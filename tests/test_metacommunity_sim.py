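import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from driftlab.drift_detection import DriftDistributionFit
from driftlab.metacommunity_sim import (
    MetacommunityState,
    ScenarioConfig,
    apply_drift,
    bray_curtis,
    disperse,
    draw_growth_rates,
    initialize_metacommunity,
    pielou_evenness,
    richness,
    run_paired_simulation,
    run_scenario_grid,
    run_species_sweep,
    step_generation,
)

UPPER_FIT = DriftDistributionFit("lognormal", {"meanlog": 0.625, "sdlog": 0.889})


def small_config(**kw):
    base = dict(n_communities=10, n_species=100, generations=50,
                drift_distribution=UPPER_FIT, seed=0)
    base.update(kw)
    return ScenarioConfig(**base)


class TestMetrics:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2, 3), (1, 2, 3), 0.0),
            ((1, 0, 0), (0, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), 1 / 3),
            ((0, 0), (0, 0), 0.0),
        ],
    )
    def test_bray_curtis_known_values(self, a, b, expected):
        assert bray_curtis(a, b) == pytest.approx(expected)

    def test_bray_curtis_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bray_curtis([1, -2], [1, 2])
        with pytest.raises(ValueError):
            bray_curtis([1, 2], [1, 2, 3])

    @given(
        a=hnp.arrays(float, 12, elements=st.floats(0, 1e6)),
        b=hnp.arrays(float, 12, elements=st.floats(0, 1e6)),
    )
    @settings(max_examples=100, deadline=None)
    def test_bray_curtis_bounds_and_identity(self, a, b):
        d = bray_curtis(a, b)
        assert -1e-12 <= d <= 1 + 1e-12
        assert bray_curtis(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_richness_and_evenness(self):
        assert richness((5, 0, 0)) == 1
        assert pielou_evenness((5, 0, 0)) == 1.0
        assert pielou_evenness(np.full(7, 3.0)) == pytest.approx(1.0)
        assert richness(np.full(7, 3.0)) == 7
        # (2,1,1): H = 1.03972..., ln3 = 1.09861..., J = 0.94639...
        assert pielou_evenness((2, 1, 1)) == pytest.approx(0.94639, abs=1e-5)
        assert richness(np.zeros(4)) == 0
        assert pielou_evenness(np.zeros(4)) == 1.0


class TestPrimitives:
    def test_initialization_shape_and_limits(self):
        cfg = small_config(n_communities=7, n_species=23)
        state = initialize_metacommunity(cfg, np.random.default_rng(0))
        assert state.abundances.shape == (7, 23)
        assert (state.abundances >= 0).all()
        assert state.generation == 0

    def test_initial_abundance_distribution(self):
        """At vanishing selection every community equals the log-normal base."""
        cfg = small_config(n_communities=3, n_species=100_000, selection_sd=1e-9)
        state = initialize_metacommunity(cfg, np.random.default_rng(1))
        log_base = np.log(state.abundances[0])
        assert log_base.mean() == pytest.approx(4.0, rel=0.01)
        assert log_base.std() == pytest.approx(1.1, rel=0.01)
        np.testing.assert_allclose(state.abundances[1], state.abundances[0], rtol=1e-7)

    def test_growth_rates_moments_and_truncation(self):
        cfg = small_config(selection_sd=0.167)
        rng = np.random.default_rng(2)
        r = draw_growth_rates(cfg, (500, 500), rng)
        assert (r >= 0).all()
        assert r.mean() == pytest.approx(1.0, abs=0.01)
        assert r.std() == pytest.approx(0.167, abs=0.01)
        cfg0 = dataclasses.replace(cfg, selection_sd=0.0)
        assert (draw_growth_rates(cfg0, (10, 10), rng) == 1.0).all()

    def test_drift_perturbation_scale(self):
        """A near-point-mass magnitude m gives rate' / rate with sd ~ m/100."""
        rng = np.random.default_rng(3)
        m = 5.0
        fit = DriftDistributionFit("lognormal", {"meanlog": np.log(m), "sdlog": 1e-9})
        rates = np.ones((400, 400))
        perturbed = apply_drift(rates, fit, rng)
        assert (perturbed >= 0).all()
        assert perturbed.std() == pytest.approx(m / 100, rel=0.02)
        assert perturbed.mean() == pytest.approx(1.0, abs=1e-3)

    def test_drift_requires_positive_support(self):
        fit = DriftDistributionFit("normal", {"mean": 2.0, "sd": 1.0})
        with pytest.raises(ValueError, match="positive support"):
            apply_drift(np.ones((2, 2)), fit, np.random.default_rng(0))

    def test_dispersal_identity_at_zero(self):
        A = np.random.default_rng(4).uniform(0, 10, (5, 8))
        state = MetacommunityState(A.copy())
        np.testing.assert_array_equal(disperse(state, 0.0).abundances, A)

    def test_dispersal_moves_fraction_to_ring_neighbor(self):
        A = np.zeros((4, 1))
        A[3, 0] = 100.0  # last community feeds the first
        state = disperse(MetacommunityState(A), 0.2)
        np.testing.assert_allclose(state.abundances[:, 0], [20, 0, 0, 80])

    @given(
        A=hnp.arrays(float, (6, 9), elements=st.floats(0, 1e9)),
        d=st.floats(0, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_dispersal_conserves_species_totals(self, A, d):
        before = A.sum(axis=0)
        after = disperse(MetacommunityState(A.copy()), d).abundances.sum(axis=0)
        np.testing.assert_allclose(after, before, rtol=1e-12, atol=1e-6)

    def test_step_rejects_mismatched_twins(self):
        cfg = small_config()
        a = MetacommunityState(np.ones((3, 4)))
        b = MetacommunityState(np.ones((3, 5)))
        with pytest.raises(ValueError, match="mismatch"):
            step_generation(a, b, cfg, np.random.default_rng(0))

    def test_quiet_generation_changes_nothing_above_threshold(self):
        """With selection_sd ~ 0, no dispersal, no drift, only the extinction
        floor acts."""
        cfg = small_config(selection_sd=1e-12, dispersal=0.0, drift_distribution=None)
        A = np.array([[0.5, 2.0, 30.0]])
        a, b = MetacommunityState(A.copy()), MetacommunityState(A.copy())
        step_generation(a, b, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(a.abundances, [[0.0, 2.0, 30.0]], rtol=1e-9)


class TestPairedRuns:
    def test_no_drift_twins_are_bit_identical(self):
        res = run_paired_simulation(small_config(drift_distribution=None))
        assert (res.trajectory["mean_bc"] == 0).all()
        assert (res.trajectory["mean_delta_s"] == 0).all()
        assert (res.trajectory["mean_delta_evenness"] == 0).all()
        assert len(res.extinct_species) == 0

    def test_fixed_seed_reproducibility(self):
        r1 = run_paired_simulation(small_config(seed=42))
        r2 = run_paired_simulation(small_config(seed=42))
        pd.testing.assert_frame_equal(r1.trajectory, r2.trajectory)
        assert r1.final_bc == r2.final_bc

    def test_trajectory_contract(self):
        cfg = small_config(generations=30)
        res = run_paired_simulation(cfg)
        assert len(res.trajectory) == 30
        assert (res.trajectory["mean_bc"].between(0, 1)).all()
        assert list(res.trajectory["generation"]) == list(range(1, 31))

    def test_extinct_records_are_exact(self):
        cfg = small_config(n_communities=20, n_species=300, generations=100, seed=5)
        res = run_paired_simulation(cfg)
        assert (res.extinct_species["initial_relabund_pct"] > 0).all()
        drift_final = res.final_drift_abundances
        nodrift_final = res.final_nodrift_abundances
        for row in res.extinct_species.itertuples():
            assert drift_final[row.community, row.species] == 0.0
            assert nodrift_final[row.community, row.species] > 0.0

    def test_global_richness_never_increases(self):
        cfg = small_config(generations=80, seed=6)
        ss = np.random.SeedSequence(cfg.seed)
        init_rng, base_rng, drift_rng = (np.random.default_rng(s) for s in ss.spawn(3))
        start = initialize_metacommunity(cfg, init_rng)
        a, b = start.copy(), start.copy()
        prev_a = richness(a.abundances.sum(axis=0))
        prev_b = prev_a
        for _ in range(cfg.generations):
            step_generation(a, b, cfg, base_rng, drift_rng)
            cur_a = richness(a.abundances.sum(axis=0))
            cur_b = richness(b.abundances.sum(axis=0))
            assert cur_a <= prev_a and cur_b <= prev_b
            prev_a, prev_b = cur_a, cur_b

    def test_drift_causes_species_loss_on_average(self):
        """ΔS <= 0 across a seed ensemble: drift only adds growth-rate variance."""
        deltas = [run_paired_simulation(
            small_config(n_communities=15, n_species=200, generations=150, seed=s)
        ).final_delta_s for s in range(5)]
        assert np.mean(deltas) < 0


class TestScenarioSweeps:
    def test_grid_runs_all_cells_reproducibly(self):
        cfg = small_config(n_communities=5, n_species=50, generations=20)
        grid = run_scenario_grid(cfg, [0.071, 0.167], [0.02, 0.2])
        assert len(grid) == 4
        assert set(zip(grid["selection_sd"], grid["dispersal"])) == {
            (0.071, 0.02), (0.071, 0.2), (0.167, 0.02), (0.167, 0.2)}
        again = run_scenario_grid(cfg, [0.071, 0.167], [0.02, 0.2])
        pd.testing.assert_frame_equal(grid, again)

    def test_grid_levels_must_be_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            run_scenario_grid(small_config(), [0.2, 0.1], [0.02])

    def test_species_sweep_layout_and_trend_columns(self):
        cfg = small_config(n_communities=5, generations=20)
        runs, trends = run_species_sweep(cfg, [(0.167, 0.02)], species_counts=(50, 100),
                                         replicates=2)
        assert len(runs) == 4
        assert set(trends.columns) >= {"selection_sd", "dispersal", "slope",
                                       "adj_r2", "p_value"}
        runs2, _ = run_species_sweep(cfg, [(0.167, 0.02)], species_counts=(50, 100),
                                     replicates=2)
        pd.testing.assert_frame_equal(runs, runs2)


def test_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(dispersal=1.0).validate()
    with pytest.raises(ValueError):
        ScenarioConfig(selection_sd=0.0).validate()
    with pytest.raises(ValueError):
        ScenarioConfig(n_species=0).validate()
    with pytest.raises(ValueError):
        ScenarioConfig(drift_distribution=DriftDistributionFit(
            "normal", {"mean": 1.0, "sd": 1.0})).validate()
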