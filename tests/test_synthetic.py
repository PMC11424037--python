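"""Generators: ground-truth systems, OU simulation, hemodynamics, BOLD forward model."""

import numpy as np
import pytest

import necdyn as nd
from necdyn.exceptions import DataError
from necdyn.hemodynamics import BalloonParams, balloon_windkessel_response


class TestRandomStableEc:
    def test_zero_asymmetry_gives_symmetric_drift(self):
        model = nd.random_stable_ec(4, asymmetry=0.0, seed=1)
        assert np.max(np.abs(model.A - model.A.T)) <= 1e-12
        assert np.max(np.abs(nd.steady_state(model).S)) <= 1e-12

    def test_forced_identity_covariance(self):
        model = nd.random_stable_ec(2, asymmetry=1.0, seed=2, sigma2=2.0,
                                    Sigma=np.eye(2))
        S = nd.steady_state(model).S
        assert np.max(np.abs(S)) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(model.A, -np.eye(2) + S, atol=1e-12)

    def test_same_seed_bitwise_identical(self):
        a = nd.random_stable_ec(6, asymmetry=0.7, sparsity=0.3, seed=9)
        b = nd.random_stable_ec(6, asymmetry=0.7, sparsity=0.3, seed=9)
        assert np.array_equal(a.A, b.A)

    def test_sparsity_zeroes_dccov_pairs(self):
        model = nd.random_stable_ec(8, asymmetry=0.8, sparsity=0.5, seed=4)
        S = nd.steady_state(model).S
        iu = np.triu_indices(8, k=1)
        zero_pairs = np.sum(np.abs(S[iu]) < 1e-12)
        assert zero_pairs >= int(0.5 * iu[0].size) - 1

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            nd.random_stable_ec(4, sparsity=1.0)
        with pytest.raises(ValueError):
            nd.random_stable_ec(4, asymmetry=-0.1)

    def test_sparse_variant_has_structural_zeros_and_stability(self):
        model = nd.random_sparse_stable_ec(6, zero_fraction=0.5, seed=7)
        off = ~np.eye(6, dtype=bool)
        assert np.sum(model.A[off] == 0.0) >= 6  # plenty of exact zeros
        assert np.max(np.linalg.eigvals(model.A).real) < 0


class TestSimulateOu:
    def test_moments_match_stationary_law(self):
        model = nd.LinearModel(A=np.array([[-1.0, 1.0], [-1.0, -1.0]]), sigma2=2.0)
        X = nd.simulate_ou(model, dt=0.1, n_steps=300_000, seed=5)
        Sigma = nd.solve_stationary_covariance(model)
        emp = np.cov(X, rowvar=False)
        rel = np.linalg.norm(emp - Sigma) / np.linalg.norm(Sigma)
        assert rel < 0.03

    def test_lag1_estimator_recovers_dccov(self):
        model = nd.LinearModel(A=np.array([[-1.0, 1.0], [-1.0, -1.0]]), sigma2=2.0)
        S_true = nd.steady_state(model).S
        X = nd.simulate_ou(model, dt=0.1, n_steps=500_000, seed=6)
        _, ss_hat = nd.fit_baseline_ou(X, dt=0.1)
        assert np.max(np.abs(ss_hat.S - S_true)) < 0.05 * np.max(np.abs(S_true))

    def test_detailed_balance_symmetric_lag1_cross_covariance(self):
        Sigma = np.array([[1.0, 0.4], [0.4, 1.0]])
        model = nd.LinearModel(A=nd.symmetric_ec(Sigma, 1.0), sigma2=1.0)
        X = nd.simulate_ou(model, dt=0.2, n_steps=300_000, seed=8)
        Xc = X - X.mean(axis=0)
        C1 = Xc[1:].T @ Xc[:-1] / (len(X) - 1)
        assert np.max(np.abs(C1 - C1.T)) < 0.02

    def test_same_seed_reproducible(self):
        model = nd.random_stable_ec(3, seed=1)
        a = nd.simulate_ou(model, dt=1.0, n_steps=100, seed=3)
        b = nd.simulate_ou(model, dt=1.0, n_steps=100, seed=3)
        assert np.array_equal(a, b)


class TestBalloonWindkessel:
    def test_zero_impulse_gives_zero_fir(self):
        assert np.all(balloon_windkessel_response(0.0) == 0.0)

    def test_canonical_shape(self):
        fir = balloon_windkessel_response(1.0, TR=1.0, L=18)
        peak = int(fir.argmax())
        assert 4 <= peak <= 6  # canonical rise
        assert fir.min() < 0  # undershoot
        assert peak < int(np.argmin(fir))  # undershoot after the peak

    def test_halved_signal_decay_shifts_peak_later(self):
        f_nom = balloon_windkessel_response(TR=0.1, L=180)
        f_slow = balloon_windkessel_response(
            params=BalloonParams(kappa=0.32), TR=0.1, L=180
        )
        assert f_slow.argmax() > f_nom.argmax()

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            balloon_windkessel_response(params=BalloonParams(tau=-1.0))


class TestHrfPrior:
    def test_mean_has_canonical_shape_and_psd_covariance(self, hrf_prior):
        assert 3 <= int(hrf_prior.mu_h.argmax()) <= 6
        assert hrf_prior.mu_h.max() > 0
        eigs = np.linalg.eigvalsh(hrf_prior.Sigma_h)
        assert eigs.min() >= -1e-12 * max(eigs.max(), 1.0)

    def test_same_seed_identical(self):
        a = nd.sample_hrf_prior(n_samples=300, seed=4)
        b = nd.sample_hrf_prior(n_samples=300, seed=4)
        assert np.array_equal(a.mu_h, b.mu_h)
        assert np.array_equal(a.Sigma_h, b.Sigma_h)

    def test_monte_carlo_convergence(self):
        ref = nd.sample_hrf_prior(n_samples=8000, seed=10).Sigma_h
        d_small = np.linalg.norm(nd.sample_hrf_prior(n_samples=300, seed=11).Sigma_h - ref)
        d_large = np.linalg.norm(nd.sample_hrf_prior(n_samples=3000, seed=12).Sigma_h - ref)
        assert d_large < d_small

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nd.sample_hrf_prior(n_samples=50)


class TestGenerateBold:
    def test_identity_fir_returns_states(self):
        rng = np.random.default_rng(0)
        states = rng.standard_normal((50, 3))
        h = np.zeros((3, 4))
        h[:, 0] = 1.0
        rec = nd.generate_bold(states, h, 0.0, TR=1.0)
        np.testing.assert_allclose(rec.data, states[3:], atol=1e-14)

    def test_dc_gain_on_constant_state(self):
        h = np.array([[0.3, 0.2, 0.1], [0.5, 0.0, 0.5]])
        states = np.full((20, 2), 2.0)
        rec = nd.generate_bold(states, h, 0.0, TR=1.0)
        expected = np.broadcast_to(2.0 * h.sum(axis=1), rec.data.shape)
        np.testing.assert_allclose(rec.data, expected, atol=1e-14)

    def test_variance_additivity_with_noise(self):
        rng = np.random.default_rng(1)
        states = rng.standard_normal((60_000, 2))
        h = np.array([[0.6, 0.4], [0.8, -0.2]])
        lam = np.array([0.25, 0.5])
        clean = nd.generate_bold(states, h, 0.0, TR=1.0)
        noisy = nd.generate_bold(states, h, lam, TR=1.0, seed=2)
        expected = clean.data.var(axis=0) + lam
        assert np.max(np.abs(noisy.data.var(axis=0) - expected) / expected) < 0.05

    def test_burn_in_dropped(self):
        states = np.zeros((30, 2))
        rec = nd.generate_bold(states, np.ones((2, 7)), 0.0, TR=2.0)
        assert rec.n_time == 30 - 6

    def test_too_short_series_rejected(self):
        with pytest.raises(DataError):
            nd.generate_bold(np.zeros((4, 2)), np.ones((2, 7)), 0.0, TR=1.0)


class TestTimeReverse:
    def test_rows_reversed_and_involutive(self):
        rec = nd.BoldRecording(
            data=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]), TR=1.0
        )
        rev = nd.time_reverse(rec)
        np.testing.assert_allclose(rev.data, [[5.0, 6.0], [3.0, 4.0], [1.0, 2.0]])
        np.testing.assert_allclose(nd.time_reverse(rev).data, rec.data)

    def test_static_fc_invariant(self):
        rng = np.random.default_rng(2)
        rec = nd.BoldRecording(data=rng.standard_normal((200, 4)), TR=1.0)
        np.testing.assert_allclose(
            nd.static_fc(rec), nd.static_fc(nd.time_reverse(rec)), atol=5e-15
        )


def test_generated_bold_fc_tracks_analytic_fc(hrf_prior):
    """Band-passed surrogate BOLD reproduces the generator's analytic FC."""
    rec, truth = nd.synthesize_recording(
        n=5, n_time=10_000, TR=1.0, seed=33, hrf_prior=hrf_prior
    )
    Sigma = truth.steady_state.Sigma
    d = np.sqrt(np.diag(Sigma))
    fc_analytic = Sigma / np.outer(d, d)
    sfc = nd.static_fc(nd.bandpass(rec, 0.01, 0.1))
    assert nd.sfc_similarity(fc_analytic, sfc) > 0.9
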