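"""Unit and property tests for the curve, likelihood and fitting machinery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from azollatpc import (
    ConvergenceError,
    FitConfig,
    FitResult,
    GrowthRecord,
    RecordTable,
    RoomParams,
    SimulationSpec,
    VarianceComponents,
    fit_tpc,
    integrated_nll,
    negative_log_likelihood,
    room_performance,
    simulate_records,
)

LOG_2PI = math.log(2.0 * math.pi)

params_strategy = st.builds(
    RoomParams,
    p_max=st.floats(min_value=0.01, max_value=2.0),
    t_opt=st.floats(min_value=0.0, max_value=50.0),
    a=st.floats(min_value=1e-5, max_value=0.5),
    b=st.floats(min_value=1e-5, max_value=0.5),
)


class TestRoomPerformance:
    def test_peak_identity(self, pinnata_params):
        assert room_performance(24.5, pinnata_params) == pytest.approx(0.25)

    def test_fall_branch_hand_value(self, pinnata_params):
        # 0.25 * exp(-0.00344 * 10^2)
        assert room_performance(34.5, pinnata_params) == pytest.approx(
            0.25 * math.exp(-0.344), rel=1e-12
        )

    def test_rise_branch_hand_value(self, pinnata_params):
        # 0.25 * exp(-0.0155 * 10^2)
        assert room_performance(14.5, pinnata_params) == pytest.approx(
            0.25 * math.exp(-1.55), rel=1e-12
        )

    def test_vectorized_matches_scalar(self, pinnata_params):
        temps = np.linspace(0, 50, 11)
        vec = room_performance(temps, pinnata_params)
        for t, v in zip(temps, vec):
            assert room_performance(float(t), pinnata_params) == v

    @given(params_strategy, st.floats(min_value=1e-9, max_value=1e-3))
    def test_continuity_at_optimum(self, p, eps):
        lo = room_performance(p.t_opt - eps, p)
        hi = room_performance(p.t_opt + eps, p)
        # |P(t-eps) - P(t+eps)| = p_max |e^{-a eps^2} - e^{-b eps^2}| <= p_max |a-b| eps^2
        assert abs(lo - hi) <= p.p_max * abs(p.a - p.b) * eps**2 + 1e-15

    @given(params_strategy)
    def test_monotone_each_side_and_positive(self, p):
        below = p.t_opt - np.array([20.0, 10.0, 5.0, 1.0, 0.0])
        above = p.t_opt + np.array([0.0, 1.0, 5.0, 10.0, 20.0])
        vb = room_performance(below, p)
        va = room_performance(above, p)
        assert np.all(np.diff(vb) > 0)  # strictly rising toward the optimum
        assert np.all(np.diff(va) < 0)  # strictly falling past it
        assert np.all(vb > 0) and np.all(va > 0)

    @given(
        st.floats(min_value=0.01, max_value=2.0),
        st.floats(min_value=0.0, max_value=50.0),
        st.floats(min_value=1e-5, max_value=0.5),
        st.floats(min_value=0.1, max_value=30.0),
    )
    def test_symmetric_when_shapes_equal(self, p_max, t_opt, shape, d):
        p = RoomParams(p_max=p_max, t_opt=t_opt, a=shape, b=shape)
        assert room_performance(t_opt - d, p) == pytest.approx(
            room_performance(t_opt + d, p), rel=1e-12
        )

    @given(params_strategy, st.floats(min_value=0.1, max_value=5.0))
    def test_scale_equivariance_in_peak(self, p, c):
        scaled = RoomParams(p.p_max * c, p.t_opt, p.a, p.b)
        temps = np.array([5.0, 20.0, 35.0, 49.0])
        # atol floor guards subnormal underflow far in the curve's tails
        np.testing.assert_allclose(
            room_performance(temps, scaled),
            c * room_performance(temps, p),
            rtol=1e-12,
            atol=1e-300,
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RoomParams(p_max=-0.1, t_opt=25.0, a=0.01, b=0.01)
        with pytest.raises(ValueError):
            RoomParams(p_max=0.2, t_opt=25.0, a=0.0, b=0.01)


class TestNegativeLogLikelihood:
    def test_single_record_on_curve_standard_normals(self, pinnata_params):
        """A zero residual and a zero offset each contribute ½ln(2π)."""
        table = RecordTable(
            records=[GrowthRecord("s1", "A_pinnata", 24.5, 0.25, "reported")]
        )
        v = VarianceComponents(sigma_resid=1.0, sigma_study=1.0)
        nll = negative_log_likelihood(table, pinnata_params, v, {"s1": 0.0})
        assert nll == pytest.approx(LOG_2PI, rel=1e-12)

    def test_additivity_over_records(self, pinnata_params):
        r1 = GrowthRecord("s1", "A_pinnata", 24.5, 0.25, "reported")
        r2 = GrowthRecord("s1", "A_pinnata", 30.0, 0.20, "reported")
        v = VarianceComponents(sigma_resid=0.05, sigma_study=0.3)
        one = negative_log_likelihood(
            RecordTable(records=[r1]), pinnata_params, v, {"s1": 0.1}
        )
        two = negative_log_likelihood(
            RecordTable(records=[r1, r2]), pinnata_params, v, {"s1": 0.1}
        )
        expected_term = -norm.logpdf(
            0.20, loc=math.exp(0.1) * room_performance(30.0, pinnata_params), scale=0.05
        )
        assert two - one == pytest.approx(expected_term, rel=1e-10)

    def test_doubling_sigma_adds_ln2_per_record(self, pinnata_params):
        """With zero residuals only the Gaussian normalizer changes."""
        recs = [
            GrowthRecord("s1", "A_pinnata", t, room_performance(t, pinnata_params), "reported")
            for t in (15.0, 24.5, 35.0)
        ]
        table = RecordTable(records=recs)
        v1 = VarianceComponents(sigma_resid=0.5, sigma_study=1.0)
        v2 = VarianceComponents(sigma_resid=1.0, sigma_study=1.0)
        nll1 = negative_log_likelihood(table, pinnata_params, v1, {"s1": 0.0})
        nll2 = negative_log_likelihood(table, pinnata_params, v2, {"s1": 0.0})
        assert nll2 - nll1 == pytest.approx(3 * math.log(2.0), rel=1e-12)

    def test_missing_offset_and_bad_sigma(self, small_table, pinnata_params):
        v = VarianceComponents(sigma_resid=0.05, sigma_study=0.3)
        with pytest.raises(ValueError, match="offsets"):
            negative_log_likelihood(small_table, pinnata_params, v, {"s1": 0.0})


def _mc_marginal_nll(table, params, variance, n_draws, seed):
    """Brute-force Monte-Carlo marginalization oracle; returns (nll, se)."""
    rng = np.random.default_rng(seed)
    total, var_total = 0.0, 0.0
    groups: dict[str, list] = {}
    for r in table:
        groups.setdefault(r.study_id, []).append(r)
    for recs in groups.values():
        u = rng.normal(0.0, variance.sigma_study, size=n_draws)
        ll = np.zeros(n_draws)
        for r in recs:
            mu = np.exp(u) * room_performance(r.temperature, params)
            ll += norm.logpdf(r.rgr, loc=mu, scale=variance.sigma_resid)
        m = ll.max()
        lik = np.exp(ll - m)
        mean = lik.mean()
        se = lik.std(ddof=1) / math.sqrt(n_draws)
        total -= m + math.log(mean)
        var_total += (se / mean) ** 2
    return total, math.sqrt(var_total)


class TestIntegratedNLL:
    def test_degenerate_random_effect_equals_fixed_effects(
        self, small_table, pinnata_params
    ):
        """sigma_study = 0 collapses exactly to the all-offsets-zero data NLL."""
        v0 = VarianceComponents(sigma_resid=0.05, sigma_study=0.0)
        got = integrated_nll(small_table, pinnata_params, v0)
        expected = sum(
            -norm.logpdf(
                r.rgr, loc=room_performance(r.temperature, pinnata_params), scale=0.05
            )
            for r in small_table
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_monte_carlo_oracle(self, small_table, pinnata_params, variance):
        quad = integrated_nll(small_table, pinnata_params, variance, n_nodes=21)
        mc, se = _mc_marginal_nll(small_table, pinnata_params, variance, 10**6, seed=7)
        assert abs(quad - mc) < 3 * se

    def test_quadrature_refinement_converged(self, small_table, pinnata_params, variance):
        n21 = integrated_nll(small_table, pinnata_params, variance, n_nodes=21)
        n61 = integrated_nll(small_table, pinnata_params, variance, n_nodes=61)
        assert abs(n21 - n61) < 1e-6

    def test_finite_under_extreme_parameters(self, small_table):
        """Log-space accumulation never returns infinity for valid inputs."""
        p = RoomParams(p_max=1.9, t_opt=2.0, a=0.9, b=0.9)
        v = VarianceComponents(sigma_resid=1e-4, sigma_study=4.0)
        assert math.isfinite(integrated_nll(small_table, p, v))


class TestFitTPC:
    def test_near_noiseless_recovery_within_one_percent(self):
        truth = RoomParams(p_max=0.25, t_opt=24.5, a=0.0155, b=0.00344)
        spec = SimulationSpec(
            true_params=truth,
            true_variance=VarianceComponents(sigma_resid=1e-3, sigma_study=1e-5),
            n_studies=6,
            n_temperatures=10,
            seed=5,
        )
        table = simulate_records(spec)
        res = fit_tpc(table, FitConfig(seed=0, n_starts=4))
        assert res.converged
        assert res.params.t_opt == pytest.approx(truth.t_opt, abs=0.245)  # 1% of 24.5
        assert res.params.p_max == pytest.approx(truth.p_max, rel=0.01)
        assert res.params.a == pytest.approx(truth.a, rel=0.01)
        assert res.params.b == pytest.approx(truth.b, rel=0.01)

    def test_reproducible_for_fixed_seed(self, simulated_table, fast_fit_config):
        r1 = fit_tpc(simulated_table, fast_fit_config)
        r2 = fit_tpc(simulated_table, FitConfig(seed=0, n_starts=4))
        assert r1.params == r2.params
        assert r1.loglik == r2.loglik

    def test_optimum_beats_random_perturbations(self, simulated_table, fast_fit_config):
        res = fit_tpc(simulated_table, fast_fit_config)
        base = integrated_nll(simulated_table, res.params, res.variance)
        rng = np.random.default_rng(42)
        for _ in range(10):
            p = RoomParams(
                p_max=res.params.p_max * math.exp(rng.normal(0, 0.1)),
                t_opt=res.params.t_opt + rng.normal(0, 1.0),
                a=res.params.a * math.exp(rng.normal(0, 0.2)),
                b=res.params.b * math.exp(rng.normal(0, 0.2)),
            )
            assert integrated_nll(simulated_table, p, res.variance) >= base - 1e-8

    def test_preconditions(self, fast_fit_config):
        with pytest.raises(ValueError, match="empty"):
            fit_tpc(RecordTable(records=[]), fast_fit_config)
        one_temp = RecordTable(
            records=[
                GrowthRecord("s1", "A_pinnata", 25.0, 0.2, "reported"),
                GrowthRecord("s2", "A_pinnata", 25.0, 0.21, "reported"),
            ]
        )
        with pytest.raises(ValueError, match="temperatures"):
            fit_tpc(one_temp, fast_fit_config)
        mixed = RecordTable(
            records=[
                GrowthRecord("s1", "A_pinnata", 20.0, 0.2, "reported"),
                GrowthRecord("s1", "A_filiculoides", 30.0, 0.2, "reported"),
            ]
        )
        with pytest.raises(ValueError, match="species"):
            fit_tpc(mixed, fast_fit_config)

    def test_json_round_trip(self, simulated_table, fast_fit_config, tmp_path):
        res = fit_tpc(simulated_table, fast_fit_config, species="A_pinnata")
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = FitResult.from_json(path)
        assert back.params == res.params
        assert back.variance == res.variance
        assert back.n_obs == res.n_obs == len(simulated_table)
        assert back.species == "A_pinnata"
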