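import numpy as np
import pytest
from scipy.stats import norm

from rhythmeg.gcmi import (RankDeficiencyError, band_phase, copula_normalize,
                           delay_gcmi, mi_gg, pca_reduce, segment_shuffle,
                           surrogate_z)


class TestCopulaNormalize:
    def test_three_sample_quantiles(self):
        out = copula_normalize([5.0, 1.0, 9.0])[:, 0]
        expected = norm.ppf([0.5, 0.25, 0.75])
        assert np.allclose(out, expected)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.standard_normal((200, 3))
        assert np.array_equal(copula_normalize(x), copula_normalize(np.exp(x)))

    def test_column_median_is_centred(self, rng):
        out = copula_normalize(rng.standard_normal((501, 2)))
        assert np.allclose(np.median(out, axis=0), 0.0, atol=1e-12)

    def test_stable_tie_breaking(self):
        out = copula_normalize([1.0, 1.0, 2.0, 0.0])[:, 0]
        # first occurrence of the tie gets the lower rank
        assert out[0] < out[1]

    def test_constant_column_rejected(self, rng):
        x = rng.standard_normal((50, 2))
        x[:, 1] = 3.0
        with pytest.raises(ValueError, match="degenerate"):
            copula_normalize(x)


class TestMiGG:
    def test_independent_inputs_near_zero(self, rng):
        x = copula_normalize(rng.standard_normal(50_000))
        y = copula_normalize(rng.standard_normal(50_000))
        assert abs(mi_gg(x, y).value) < 0.005

    def test_bivariate_gaussian_closed_form(self, rng):
        n, r = 50_000, 0.5
        z = rng.standard_normal((n, 2))
        x = z[:, 0]
        y = r * x + np.sqrt(1 - r * r) * z[:, 1]
        est = mi_gg(copula_normalize(x), copula_normalize(y)).value
        assert est == pytest.approx(-0.5 * np.log2(1 - r * r), abs=0.01)

    def test_duplicated_variable_raises_rank_deficiency(self, rng):
        x = copula_normalize(rng.standard_normal(100))
        with pytest.raises(RankDeficiencyError):
            mi_gg(x, x)

    def test_uncorrected_estimate_is_nonnegative(self, rng):
        for _ in range(20):
            x = copula_normalize(rng.standard_normal((30, 2)))
            y = copula_normalize(rng.standard_normal((30, 2)))
            assert mi_gg(x, y, bias_correct=False).value >= 0

    def test_corrected_negativity_is_within_bias_magnitude(self, rng):
        from rhythmeg.gcmi import _mi_bias_nats
        worst = 0.0
        for _ in range(20):
            x = copula_normalize(rng.standard_normal((40, 2)))
            y = copula_normalize(rng.standard_normal((40, 2)))
            worst = min(worst, mi_gg(x, y).value)
        bias_bits = _mi_bias_nats(40, 2, 2) / np.log(2)
        assert bias_bits > 0  # raw Gaussian MI overestimates
        assert worst >= -bias_bits * 1.05

    def test_sample_size_precondition(self, rng):
        x = copula_normalize(rng.standard_normal((6, 2)))
        with pytest.raises(ValueError, match="n > dx"):
            mi_gg(x, x.copy() + rng.standard_normal((6, 2)))


class TestPCAReduce:
    def test_rank_deficient_data_truncated_with_warning(self, rng):
        base = rng.standard_normal((200, 2))
        data = base @ rng.standard_normal((2, 5))
        with pytest.warns(RuntimeWarning, match="rank"):
            scores, var = pca_reduce(data, 3)
        assert scores.shape[1] == 2
        assert var.sum() == pytest.approx(1.0)

    def test_recovers_designed_subspace(self, rng):
        # two strong orthogonal directions + weak noise
        u = np.linalg.qr(rng.standard_normal((6, 6)))[0][:, :2]
        latent = rng.standard_normal((500, 2)) * [10.0, 5.0]
        data = latent @ u.T + 0.01 * rng.standard_normal((500, 6))
        scores, var = pca_reduce(data, 2)
        v = np.linalg.qr(np.linalg.lstsq(scores, data, rcond=None)[0].T)[0]
        angles = np.linalg.svd(u.T @ v)[1]
        assert np.all(angles > 1 - 1e-4)  # cosines of principal angles
        assert np.all(np.diff(var) <= 1e-12)

    def test_k_larger_than_voxels_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.standard_normal((50, 3)), 4)


class TestBandPhase:
    def test_pure_sinusoid_phase_velocity(self):
        fs, f0 = 100.0, 6.0
        t = np.arange(0, 10, 1 / fs)
        sp = band_phase(np.sin(2 * np.pi * f0 * t), fs, f0)
        ph = np.unwrap(np.arctan2(sp.phase_pairs[:, 1], sp.phase_pairs[:, 0]))
        rate = np.diff(ph[sp.valid]).mean() * fs / (2 * np.pi)
        assert rate == pytest.approx(f0, rel=0.01)

    def test_out_of_band_attenuation(self):
        fs, f0, bw = 100.0, 6.0, 2.0
        t = np.arange(0, 10, 1 / fs)
        in_band = band_phase(np.sin(2 * np.pi * f0 * t), fs, f0, bw,
                             phase_only=False)
        out_band = band_phase(np.sin(2 * np.pi * (f0 + 3 * bw) * t), fs, f0,
                              bw, phase_only=False)
        p_in = np.mean(in_band.trimmed() ** 2)
        p_out = np.mean(out_band.trimmed() ** 2)
        assert p_out < 0.05 * p_in

    def test_amplitude_modulation_leaves_phase_unchanged(self):
        fs, f0 = 100.0, 6.0
        t = np.arange(0, 10, 1 / fs)
        carrier = np.sin(2 * np.pi * f0 * t)
        am = (1 + 0.5 * np.sin(2 * np.pi * 0.2 * t)) * carrier
        ph = []
        for sig in (carrier, am):
            sp = band_phase(sig, fs, f0)
            ph.append(np.arctan2(sp.phase_pairs[sp.valid, 1],
                                 sp.phase_pairs[sp.valid, 0]))
        diff = np.angle(np.exp(1j * (ph[0] - ph[1])))
        assert np.max(np.abs(diff)) < 0.05

    def test_unit_norm_pairs(self, rng):
        sp = band_phase(rng.standard_normal((500, 2)), 100.0, 6.0)
        norms = sp.phase_pairs[:, 0::2] ** 2 + sp.phase_pairs[:, 1::2] ** 2
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_epoch_too_short_reports_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            band_phase(np.zeros(30), 100.0, 4.0)


class TestDelayGCMI:
    def test_zero_delay_equals_plain_mi(self, rng):
        x = rng.standard_normal((400, 2))
        y = 0.5 * x + rng.standard_normal((400, 2))
        row = delay_gcmi(x, y, [0.0], fs=100.0)
        direct = mi_gg(copula_normalize(x), copula_normalize(y)).value
        assert row[0] == pytest.approx(direct, abs=1e-12)

    def test_non_integer_delay_rejected(self, rng):
        x = rng.standard_normal((400, 1))
        with pytest.raises(ValueError, match="integer"):
            delay_gcmi(x, x + 0.0, [0.0123], fs=100.0)

    def test_recovers_shift_of_identical_series(self, rng):
        fs = 100.0
        base = rng.standard_normal(1100)
        x = base[5:1005, None]
        y = base[:1000, None] + 0.3 * rng.standard_normal((1000, 1))
        delays = np.arange(0, 0.31, 0.01)
        row = delay_gcmi(x, y, delays, fs=fs)
        assert delays[np.argmax(row)] * 1000 == pytest.approx(50, abs=10)

    def test_excessive_delay_rejected(self, rng):
        x = rng.standard_normal((100, 1))
        with pytest.raises(ValueError):
            delay_gcmi(x, x.copy(), [0.95], fs=100.0)


class TestSegmentShuffle:
    def test_two_segments_swap_half_the_time(self):
        rng = np.random.default_rng(0)
        x = np.arange(20.0)
        swaps = 0
        for _ in range(1000):
            out = segment_shuffle(x, 0.1, 100.0, rng)
            swaps += out[0] != 0.0
        assert 0.45 <= swaps / 1000 <= 0.55

    def test_rearrangement_only(self):
        rng = np.random.default_rng(1)
        x = np.arange(55.0)
        out = segment_shuffle(x, 0.1, 100.0, rng)
        assert set(out) <= set(x)
        assert len(out) == 50  # tail dropped

    def test_seeding_contract(self):
        x = np.arange(100.0)
        a = segment_shuffle(x, 0.1, 100.0, np.random.default_rng(7))
        b = segment_shuffle(x, 0.1, 100.0, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError):
            segment_shuffle(np.arange(15.0), 0.1, 100.0,
                            np.random.default_rng(0))


class TestSurrogateZ:
    def test_centering_and_scaling(self):
        surr = [1.0, 2.0, 3.0]
        assert surrogate_z(2.0, surr) == 0.0
        assert surrogate_z(2.0 + 2.0 * np.std(surr, ddof=1), surr) == pytest.approx(2.0)

    def test_invariance_to_common_affine_rescaling(self, rng):
        surr = rng.standard_normal(100)
        z0 = surrogate_z(1.3, surr)
        assert surrogate_z(1.3 + 5.0, surr + 5.0) == pytest.approx(z0)
        assert surrogate_z(1.3 * 3.0, surr * 3.0) == pytest.approx(z0)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            surrogate_z(1.0, [2.0, 2.0, 2.0])
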