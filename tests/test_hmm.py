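import numpy as np
import pytest

import _oracles
from batforage import hmm


class TestWrappedCauchy:
    def test_rho_zero_is_uniform(self):
        phi = np.linspace(-np.pi, np.pi, 7)
        np.testing.assert_allclose(
            hmm.wrapped_cauchy_density(phi, 0.3, 0.0), 1 / (2 * np.pi)
        )

    def test_peak_value_at_location(self):
        # (1/2π)·(1−ρ²)/(1−ρ)² at φ = μ; for ρ = 0.5 this is 3/(2π)
        assert hmm.wrapped_cauchy_density(1.0, 1.0, 0.5) == pytest.approx(
            3 / (2 * np.pi)
        )

    def test_normalizes_to_one(self):
        phi = np.linspace(-np.pi, np.pi, 100_001)
        for rho in (0.0, 0.3, 0.9):
            integral = np.trapezoid(hmm.wrapped_cauchy_density(phi, -0.7, rho), phi)
            assert integral == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_invalid_concentration(self, rho):
        with pytest.raises(ValueError):
            hmm.wrapped_cauchy_density(0.0, 0.0, rho)

    def test_sampler_matches_density_moments(self):
        rng = np.random.default_rng(0)
        draws = hmm.sample_wrapped_cauchy(0.8, 0.6, 50_000, rng)
        # mean resultant length of wrapped Cauchy is ρ, direction μ
        r = np.hypot(np.cos(draws).mean(), np.sin(draws).mean())
        mu = np.arctan2(np.sin(draws).mean(), np.cos(draws).mean())
        assert r == pytest.approx(0.6, abs=0.01)
        assert mu == pytest.approx(0.8, abs=0.02)


class TestForwardAlgorithm:
    def test_matches_enumeration_on_short_series(self):
        """Forward log-likelihood equals the sum over all state paths."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            kernel = _oracles.random_kernel(rng)
            T = int(rng.integers(2, 8))
            steps, angles = _oracles.random_observations(rng, T)
            series = _oracles.series_from_obs(steps, angles)
            expected = _oracles.brute_force_loglik(kernel, steps, angles)
            assert hmm.log_likelihood(kernel, series) == pytest.approx(
                expected, abs=1e-8
            )

    def test_one_state_collapses_to_independent_emissions(self):
        rng = np.random.default_rng(1)
        kernel = _oracles.random_kernel(rng, n_states=1)
        steps, angles = _oracles.random_observations(rng, 12)
        series = _oracles.series_from_obs(steps, angles)
        expected = sum(
            np.log(_oracles._emission_prob(kernel, 0, s, a))
            for s, a in zip(steps, angles)
        )
        assert hmm.log_likelihood(kernel, series) == pytest.approx(expected)

    def test_all_missing_series_loglik_zero(self):
        rng = np.random.default_rng(2)
        kernel = _oracles.random_kernel(rng)
        steps = np.full(6, np.nan)
        series = _oracles.series_from_obs(steps, steps.copy())
        assert hmm.log_likelihood(kernel, series) == pytest.approx(0.0, abs=1e-10)

    def test_invariant_under_state_relabelling(self):
        rng = np.random.default_rng(3)
        kernel = _oracles.random_kernel(rng)
        steps, angles = _oracles.random_observations(rng, 20)
        series = _oracles.series_from_obs(steps, angles)
        swapped = hmm.MovementKernel(
            gamma_shape=kernel.gamma_shape[::-1],
            gamma_scale=kernel.gamma_scale[::-1],
            wc_mu=kernel.wc_mu[::-1],
            wc_rho=kernel.wc_rho[::-1],
            tmat=kernel.tmat[::-1, ::-1],
            delta=kernel.delta[::-1],
        )
        assert hmm.log_likelihood(kernel, series) == pytest.approx(
            hmm.log_likelihood(swapped, series)
        )


class TestDecode:
    def test_viterbi_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            kernel = _oracles.random_kernel(rng)
            T = int(rng.integers(3, 6))
            steps = rng.gamma(2.0, 300.0, size=T)
            angles = rng.uniform(-np.pi, np.pi, size=T)
            series = _oracles.series_from_obs(steps, angles)
            expected = _oracles.brute_force_viterbi(kernel, steps, angles)
            got = hmm.decode(kernel, series).states[1:]  # slot 0 mirrors slot 1
            np.testing.assert_array_equal(got, expected)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(8)
        kernel = _oracles.random_kernel(rng)
        steps, angles = _oracles.random_observations(rng, 30)
        series = _oracles.series_from_obs(steps, angles)
        seq = hmm.decode(kernel, series)
        np.testing.assert_allclose(seq.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_well_separated_regimes_recovered(self):
        kernel = hmm.MovementKernel(
            gamma_shape=[1.2, 40.0], gamma_scale=[70.0, 30.0],
            wc_mu=[0.0, 0.0], wc_rho=[0.25, 0.92],
            tmat=[[0.95, 0.05], [0.07, 0.93]],
        )
        series, states = hmm.simulate_series(kernel, 400, seed=5)
        seq = hmm.decode(kernel, series)
        agree = np.mean(seq.states[2:] == states[2:])
        assert agree >= 0.95

    def test_single_state_model_decodes_constant(self):
        rng = np.random.default_rng(9)
        kernel = _oracles.random_kernel(rng, n_states=1)
        steps, angles = _oracles.random_observations(rng, 10)
        seq = hmm.decode(kernel, _oracles.series_from_obs(steps, angles))
        assert np.all(seq.states == 0)

    def test_missing_slots_flagged_imputed(self):
        rng = np.random.default_rng(10)
        kernel = _oracles.random_kernel(rng)
        steps, angles = _oracles.random_observations(rng, 20)
        steps[4] = np.nan
        angles[4] = np.nan
        seq = hmm.decode(kernel, _oracles.series_from_obs(steps, angles))
        assert seq.imputed[5]  # obs t maps to slot t+1
        assert seq.states[5] in (0, 1)


class TestFit:
    def test_parameter_recovery_from_known_kernel(self):
        true = hmm.MovementKernel(
            gamma_shape=[1.5, 30.0], gamma_scale=[60.0, 40.0],
            wc_mu=[0.0, 0.0], wc_rho=[0.3, 0.9],
            tmat=[[0.92, 0.08], [0.10, 0.90]],
        )
        series = [hmm.simulate_series(true, 250, seed=100 + i)[0] for i in range(5)]
        model = hmm.fit(series, n_states=2, n_restarts=3, seed=0)
        np.testing.assert_allclose(
            model.kernel.mean_step, true.mean_step, rtol=0.10
        )
        np.testing.assert_allclose(model.kernel.wc_rho, true.wc_rho, atol=0.1)

    def test_foraging_labelled_first(self, pooled_hmm):
        k = pooled_hmm.kernel
        assert k.mean_step[hmm.FORAGING] < k.mean_step[hmm.COMMUTING]
        assert np.allclose(k.tmat.sum(axis=1), 1.0, atol=1e-10)

    def test_aic_identity(self, pooled_hmm):
        assert pooled_hmm.aic == pytest.approx(
            2 * pooled_hmm.n_parameters - 2 * pooled_hmm.log_likelihood
        )
        assert pooled_hmm.n_parameters == 10  # 4 emission/state + 2 off-diagonals

    def test_three_state_data_prefers_three_states(self):
        """AIC ordering on well-separated three-regime data."""
        true3 = hmm.MovementKernel(
            gamma_shape=[2.0, 20.0, 60.0], gamma_scale=[20.0, 30.0, 50.0],
            wc_mu=[0.0, 0.0, 0.0], wc_rho=[0.1, 0.5, 0.95],
            tmat=[[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]],
        )
        series = [hmm.simulate_series(true3, 300, seed=200 + i)[0] for i in range(4)]
        m2 = hmm.fit(series, n_states=2, n_restarts=3, seed=1)
        m3 = hmm.fit(series, n_states=3, n_restarts=4, seed=1)
        assert m3.aic < m2.aic

    def test_constant_steps_degenerate(self):
        steps = np.full(50, 100.0)
        angles = np.zeros(50)
        series = _oracles.series_from_obs(steps, angles)
        with pytest.raises(hmm.DegeneracyError):
            hmm.fit([series], n_states=2, seed=0)

    def test_too_few_observations(self):
        steps = np.array([100.0, 200.0, 150.0])
        series = _oracles.series_from_obs(steps, np.zeros(3))
        with pytest.raises(hmm.InsufficientObservations):
            hmm.fit([series], n_states=2, seed=0)

    def test_kernel_dict_round_trip(self, pooled_hmm):
        d = hmm.kernel_to_dict(pooled_hmm.kernel)
        k2 = hmm.kernel_from_dict(d)
        np.testing.assert_allclose(k2.tmat, pooled_hmm.kernel.tmat)
        np.testing.assert_allclose(k2.gamma_shape, pooled_hmm.kernel.gamma_shape)
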