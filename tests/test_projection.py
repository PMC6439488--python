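import numpy as np
import pytest

import driftwatch as dw
from driftwatch.projection import CenturyProjection


def _traj(values):
    v = np.asarray(values, dtype=float)
    return dw.HeTrajectory(np.arange(len(v)), v, v, v, v[None, :])


class TestAnalyticDecay:
    def test_century_losses_match_theory(self):
        ht50 = dw.analytic_decay(dw.ProjectionParams(0.3, 50, 100))
        ht10 = dw.analytic_decay(dw.ProjectionParams(0.3, 10, 100))
        assert ht50 == pytest.approx(0.10981, abs=1e-4)
        assert ht10 == pytest.approx(0.0017762, abs=1e-6)
        assert 1 - ht50 / 0.3 == pytest.approx(0.634, abs=5e-3)
        assert 1 - ht10 / 0.3 == pytest.approx(0.994, abs=5e-3)

    def test_zero_generations_identity(self):
        assert dw.analytic_decay(dw.ProjectionParams(0.3, 50, 0)) == 0.3


def test_initial_expected_het_values():
    assert dw.initial_expected_het(0.81) == pytest.approx(0.3078, abs=1e-12)
    assert dw.initial_expected_het(0.5) == 0.5
    assert dw.initial_expected_het(0.0) == 0.0


class TestLossQueries:
    def test_loss_arithmetic(self):
        traj = _traj([0.30] + [0.0] * 99 + [0.237])
        assert dw.loss_at_year(traj, 100) == pytest.approx(0.21, abs=1e-12)
        assert dw.loss_at_year(traj, 0) == 0.0

    def test_zero_initial_het_defined_as_zero(self):
        traj = _traj([0.0, 0.0])
        assert dw.loss_at_year(traj, 1) == 0.0

    def test_out_of_range_year_rejected(self):
        with pytest.raises(ValueError):
            dw.loss_at_year(_traj([0.3, 0.2]), 5)

    def test_linear_trajectory_crossing(self):
        # 0.3 -> 0.1 linearly over 100 years: first value <= 0.15 at year 75
        traj = _traj(np.linspace(0.3, 0.1, 101))
        assert dw.time_to_loss_fraction(traj, 0.5) == 75

    def test_not_reached_returns_none(self):
        traj = _traj(np.linspace(0.3, 0.25, 101))
        assert dw.time_to_loss_fraction(traj, 0.5) is None


class TestSimulator:
    def test_monomorphic_initialization_stays_zero(self):
        traj = dw.simulate_overlapping(
            dw.LifeHistory(),
            dw.SimConfig(pop_size=20, n_loci=50, p_init=0.999999, n_years=20,
                         n_iterations=2, seed=1),
        )
        # p ~ 1: virtually every locus starts fixed; any residual het only decays
        assert traj.mean_het[0] < 0.001
        assert traj.mean_het[-1] <= traj.mean_het[0] + 1e-12

    def test_reproducible_given_seed(self):
        cfg = dw.SimConfig(pop_size=20, n_loci=100, n_years=20, n_iterations=3, seed=7)
        a = dw.simulate_overlapping(dw.LifeHistory(), cfg)
        b = dw.simulate_overlapping(dw.LifeHistory(), cfg)
        assert np.array_equal(a.per_iteration, b.per_iteration)

    def test_trajectory_shape_and_band(self):
        cfg = dw.SimConfig(pop_size=30, n_loci=200, n_years=30, n_iterations=4, seed=2)
        traj = dw.simulate_overlapping(dw.LifeHistory(), cfg)
        assert len(traj.years) == 31
        assert traj.per_iteration.shape == (4, 31)
        assert np.all(traj.ci_low <= traj.mean_het + 1e-12)
        assert np.all(traj.mean_het <= traj.ci_high + 1e-12)
        assert np.all((traj.mean_het >= 0) & (traj.mean_het <= 1))

    def test_newborn_initialization_supported(self):
        # a single founding cohort is only viable until it ages out
        cfg = dw.SimConfig(pop_size=12, n_loci=50, n_years=4, n_iterations=2,
                           seed=3, initial_ages="newborn")
        traj = dw.simulate_overlapping(dw.LifeHistory(), cfg)
        assert len(traj.years) == 5

    def test_drift_faster_in_smaller_populations(self):
        losses = {}
        for N in (10, 30, 50):
            traj = dw.simulate_overlapping(
                dw.LifeHistory(),
                dw.SimConfig(pop_size=N, n_loci=300, n_years=60, n_iterations=5, seed=11),
            )
            losses[N] = dw.loss_at_year(traj, 60)
        assert losses[10] > losses[30] > losses[50]

    def test_degenerate_config_raises(self):
        # a 2-individual population of newborns can never produce a breeding pair
        # before both individuals age out
        with pytest.raises(RuntimeError):
            dw.simulate_overlapping(
                dw.LifeHistory(age_first_repro=5, max_age=5),
                dw.SimConfig(pop_size=2, n_loci=10, n_years=30, n_iterations=2,
                             seed=4, initial_ages="newborn"),
            )


class TestCenturyProjection:
    def test_horizon_step_is_fifty_at_default_generation_time(self):
        traj = _traj(np.linspace(0.3, 0.2, 101))
        c = dw.century_projection(traj, pop_size=50)
        assert c.horizon_step == 50
        assert c.horizon_years == pytest.approx(50 * 2.03)
        assert c.loss == pytest.approx(dw.loss_at_year(traj, 50))

    def test_crossing_converted_to_years(self):
        traj = _traj(np.linspace(0.3, 0.1, 101))
        c = dw.century_projection(traj, pop_size=10)
        assert c.half_loss_reached
        assert c.time_to_half_years == pytest.approx(75 * 2.03)

    def test_no_crossing_reports_horizon_lower_bound(self):
        traj = _traj(np.linspace(0.3, 0.28, 101))
        c = dw.century_projection(traj, pop_size=50)
        assert not c.half_loss_reached
        assert c.time_to_half_years == pytest.approx(100 * 2.03)
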