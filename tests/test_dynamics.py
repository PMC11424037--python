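"""Filtering, FC summaries, FCD distances and Kuramoto phase statistics."""

import numpy as np
import pytest

import necdyn as nd
from necdyn.exceptions import DataError


def sinusoid_recording(freq_hz, T=2000, TR=1.0, n=2, amp=1.0):
    t = np.arange(T) * TR
    data = amp * np.column_stack([np.cos(2 * np.pi * freq_hz * t)] * n)
    data[:, 1:] += 1e-6 * np.sin(2 * np.pi * 0.033 * t)[:, None]  # break ties
    return nd.BoldRecording(data=data, TR=TR)


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        rec = sinusoid_recording(0.05)
        out = nd.bandpass(rec, 0.01, 0.1)
        mid = slice(400, -400)
        ratio = out.data[mid, 0].std() / rec.data[mid, 0].std()
        assert abs(ratio - 1.0) < 0.05

    def test_out_of_band_attenuated_20db(self):
        rec = sinusoid_recording(0.5, TR=0.5)
        out = nd.bandpass(rec, 0.01, 0.1)
        mid = slice(400, -400)
        assert out.data[mid, 0].std() / rec.data[mid, 0].std() < 0.1

    def test_dc_offset_removed(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((500, 3))
        out0 = nd.bandpass(nd.BoldRecording(data=base, TR=1.0), 0.01, 0.1)
        out7 = nd.bandpass(nd.BoldRecording(data=base + 7.0, TR=1.0), 0.01, 0.1)
        np.testing.assert_allclose(out7.data, out0.data, atol=1e-9)

    def test_infeasible_band_rejected(self):
        rec = sinusoid_recording(0.05, TR=10.0)
        with pytest.raises(DataError):
            nd.bandpass(rec, 0.01, 0.1)  # 0.1 Hz above Nyquist at TR = 10 s


class TestStaticFc:
    def test_identical_columns_correlate_fully(self):
        x = np.random.default_rng(1).standard_normal(100)
        rec = nd.BoldRecording(data=np.column_stack([x, x]), TR=1.0)
        np.testing.assert_allclose(nd.static_fc(rec), 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        T = 20_000
        rec = nd.BoldRecording(data=rng.standard_normal((T, 3)), TR=1.0)
        sfc = nd.static_fc(rec)
        off = sfc[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 3.0 / np.sqrt(T)

    def test_constant_column_names_region(self):
        data = np.random.default_rng(3).standard_normal((50, 2))
        data[:, 1] = 4.0
        rec = nd.BoldRecording(data=data, TR=1.0, labels=["a", "flatline"])
        with pytest.raises(DataError, match="flatline"):
            nd.static_fc(rec)


class TestSfcSimilarity:
    def test_identity_and_sign_flip(self):
        rng = np.random.default_rng(4)
        M = rng.standard_normal((5, 5))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        assert nd.sfc_similarity(M, M) == pytest.approx(1.0)
        assert nd.sfc_similarity(M, -M) == pytest.approx(-1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(DataError):
            nd.sfc_similarity(np.eye(3), np.eye(4))


class TestDynamicFc:
    def test_window_count_arithmetic(self):
        T, TR = 400, 1.0
        rec = nd.BoldRecording(
            data=np.random.default_rng(5).standard_normal((T, 3)), TR=TR
        )
        fc = nd.dynamic_fc(rec, window_s=50, step_s=25)
        expected = int((T * TR - 50) // 25) + 1
        assert fc.fcd.shape == (expected, expected)

    def test_white_noise_fcd_near_zero(self):
        rng = np.random.default_rng(6)
        rec = nd.BoldRecording(data=rng.standard_normal((3000, 20)), TR=1.0)
        fc = nd.dynamic_fc(rec)
        off = fc.fcd[np.triu_indices_from(fc.fcd, k=1)]
        # window patterns are independent; FCD entries fluctuate ~ 1/sqrt(pairs)
        assert abs(off.mean()) < 0.05
        assert np.abs(off).mean() < 0.15

    def test_repeated_segments_correlate_fully(self):
        rng = np.random.default_rng(7)
        half = rng.standard_normal((100, 4))
        rec = nd.BoldRecording(data=np.vstack([half, half]), TR=1.0)
        fc = nd.dynamic_fc(rec, window_s=100, step_s=100)
        np.testing.assert_allclose(fc.fcd, 1.0, atol=1e-12)

    def test_short_window_rejected(self):
        rec = nd.BoldRecording(
            data=np.random.default_rng(8).standard_normal((100, 3)), TR=25.0
        )
        with pytest.raises(DataError):
            nd.dynamic_fc(rec, window_s=50, step_s=25)


class TestKsDistance:
    def test_identical_distributions_zero(self):
        M = np.random.default_rng(9).uniform(-1, 1, size=(10, 10))
        M = (M + M.T) / 2
        assert nd.dfc_ks_distance(M, M) == 0.0

    def test_point_masses_distance_one(self):
        a = np.zeros((5, 5))
        b = np.ones((5, 5))
        assert nd.dfc_ks_distance(a, b) == 1.0

    def test_same_generator_small_distinct_generators_large(self):
        rng = np.random.default_rng(10)
        same_a = nd.BoldRecording(data=rng.standard_normal((2000, 8)), TR=1.0)
        same_b = nd.BoldRecording(data=rng.standard_normal((2000, 8)), TR=1.0)
        common = rng.standard_normal((2000, 1))
        corr = nd.BoldRecording(
            data=0.8 * common + 0.6 * rng.standard_normal((2000, 8)), TR=1.0
        )
        d_same = nd.dfc_ks_distance(
            nd.dynamic_fc(same_a).fcd, nd.dynamic_fc(same_b).fcd
        )
        d_diff = nd.dfc_ks_distance(
            nd.dynamic_fc(same_a).fcd, nd.dynamic_fc(corr).fcd
        )
        assert d_same < 0.2
        assert d_diff > 2 * d_same


class TestInstantaneousPhase:
    def test_cosine_phase_advances_linearly(self):
        TR = 1.0
        w = 2 * np.pi * 0.05
        t = np.arange(600) * TR
        data = np.column_stack([np.cos(w * t), np.cos(w * t + 0.4)])
        rec = nd.BoldRecording(data=data, TR=TR)
        ph = nd.instantaneous_phase(rec)
        tt = t[5:-5]
        expected = np.angle(np.exp(1j * w * tt))
        err = np.angle(np.exp(1j * (ph[:, 0] - expected)))
        assert np.max(np.abs(err)) < 0.05

    def test_sine_lags_cosine_by_half_pi(self):
        t = np.arange(800) * 1.0
        w = 2 * np.pi * 0.04
        rec = nd.BoldRecording(
            data=np.column_stack([np.cos(w * t), np.sin(w * t)]), TR=1.0
        )
        ph = nd.instantaneous_phase(rec)
        d = np.angle(np.exp(1j * (ph[:, 0] - ph[:, 1])))
        assert np.median(np.abs(d - np.pi / 2)) < 0.05

    def test_negation_shifts_phase_by_pi(self):
        rng = np.random.default_rng(11)
        rec = nd.BoldRecording(data=rng.standard_normal((500, 2)), TR=1.0)
        bp = nd.bandpass(rec, 0.01, 0.1)
        ph = nd.instantaneous_phase(bp)
        neg = nd.BoldRecording(data=-bp.data, TR=1.0)
        ph_neg = nd.instantaneous_phase(neg)
        d = np.angle(np.exp(1j * (ph_neg - ph - np.pi)))
        assert np.max(np.abs(d)) < 1e-9

    def test_constant_signal_rejected(self):
        rec = nd.BoldRecording(data=np.ones((100, 2)), TR=1.0)
        with pytest.raises(DataError):
            nd.instantaneous_phase(rec)


class TestKuramoto:
    def test_full_synchrony(self):
        ph = np.tile(np.linspace(0, 3, 50)[:, None], (1, 4))
        kur = nd.kuramoto_order(ph)
        np.testing.assert_allclose(kur.R_t, 1.0, atol=1e-12)
        assert kur.synchronization == pytest.approx(1.0)
        assert kur.metastability == pytest.approx(0.0, abs=1e-12)

    def test_evenly_spaced_phases_cancel(self):
        n = 8
        base = 2 * np.pi * np.arange(n) / n
        ph = base[None, :] + np.linspace(0, 2, 30)[:, None]
        kur = nd.kuramoto_order(ph)
        np.testing.assert_allclose(kur.R_t, 0.0, atol=1e-12)

    def test_uniform_phases_rayleigh_mean(self):
        rng = np.random.default_rng(12)
        n = 100
        ph = rng.uniform(0, 2 * np.pi, size=(4000, n))
        kur = nd.kuramoto_order(ph)
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        assert abs(kur.synchronization - expected) / expected < 0.2


def test_hrf_filtering_raises_synchrony_and_metastability(hrf_prior):
    """On OU surrogates, hemodynamic smoothing concentrates power at low
    frequencies and increases both Kuramoto indices relative to the raw state."""
    model = nd.random_stable_ec(6, asymmetry=0.5, seed=14)
    L = hrf_prior.L
    states = nd.simulate_ou(model, dt=1.0, n_steps=4000 + L - 1, seed=15)
    state_rec = nd.BoldRecording(data=states[L - 1:], TR=1.0)
    bold = nd.generate_bold(states, np.tile(hrf_prior.mu_h, (6, 1)), 0.0, TR=1.0)
    k_state = nd.kuramoto_order(
        nd.instantaneous_phase(nd.bandpass(state_rec, 0.01, 0.1))
    )
    k_bold = nd.kuramoto_order(
        nd.instantaneous_phase(nd.bandpass(bold, 0.01, 0.1))
    )
    assert k_bold.synchronization > k_state.synchronization
    assert k_bold.metastability > k_state.metastability
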