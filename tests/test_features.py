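"""VAR / PSD / DWT feature extractors, normalization and fusion."""

import numpy as np
import pytest

from oddball_eeg import wavelets
from oddball_eeg.features import (FeatureConfig, FeatureMatrix,
                                  apply_normalizer, dwt_features,
                                  fit_normalizer, fuse, psd_features,
                                  var_features)
from oddball_eeg.montage import FEATURE_CHANNELS
from tests.conftest import make_epochset

FS = 250.0
N_CH = len(FEATURE_CHANNELS)


def _es(data, labels=None):
    labels = labels or ["control"] * data.shape[0]
    return make_epochset(data, labels, channel_names=list(FEATURE_CHANNELS))


def _noise_es(n_trials=16, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return _es(scale * rng.standard_normal((n_trials, N_CH, 375)))


class TestVar:
    def test_study_profile_dimensionality(self):
        """4 windows x 11 channels = 44 variance features."""
        fm = var_features(_noise_es())
        assert fm.n_features == 44
        assert fm.names[0].startswith("var:PO3")

    def test_constant_epoch_zero_vector(self):
        fm = var_features(_es(np.full((2, N_CH, 375), 3.0)))
        np.testing.assert_allclose(fm.matrix, 0.0, atol=1e-20)

    def test_unit_variance_noise_expectation(self):
        """Each variance feature averages to ~1 over many unit-variance
        white-noise trials (Monte-Carlo expectation within 10%)."""
        fm = var_features(_noise_es(n_trials=1000, seed=1))
        np.testing.assert_allclose(fm.matrix.mean(axis=0), 1.0, rtol=0.10)

    def test_offset_invariance(self):
        es = _noise_es(seed=2)
        shifted = _es(es.epochs + 42.0)
        np.testing.assert_allclose(var_features(es).matrix,
                                   var_features(shifted).matrix, rtol=1e-9)

    def test_missing_channel_named(self):
        es = make_epochset(np.zeros((2, 3, 375)), ["control"] * 2,
                           channel_names=["O2", "Pz", "Cz"])
        with pytest.raises(ValueError, match="PO3"):
            var_features(es)


class TestPsd:
    def test_printed_dims_25_bins_per_channel(self):
        """The pinned FFT grid yields exactly 25 bins in 1-30 Hz, i.e.
        275 features over 11 channels."""
        fm = psd_features(_noise_es())
        assert fm.meta["bins_per_channel"] == 25
        assert fm.n_features == 275

    def test_pure_tone_peaks_at_matching_bin(self):
        t = np.arange(375) / FS
        data = np.tile(np.sin(2 * np.pi * 10.0 * t), (2, N_CH, 1))
        fm = psd_features(_es(data))
        freqs = np.array([float(n.split(":")[2][:-2]) for n in fm.names[:25]])
        for trial in fm.matrix:
            per_channel = trial.reshape(N_CH, 25)
            for row in per_channel:
                assert freqs[np.argmax(row)] == pytest.approx(10.0, abs=0.7)

    def test_parseval_consistency(self):
        """Full-band Welch estimates integrate to the signal variance
        (within 10%, averaged over trials)."""
        cfg = FeatureConfig(psd_band_hz=(0.0, 125.0), psd_nfft=None)
        es = _noise_es(n_trials=400, seed=3)
        fm = psd_features(es, cfg)
        df = fm.meta["df_hz"]
        bins = fm.meta["bins_per_channel"]
        total = fm.matrix.reshape(len(fm.labels), N_CH, bins).sum(axis=2) * df
        # detrended variance of the analysis window
        slab = es.epochs[:, :, 125:290]
        var = slab.var(axis=2)
        assert np.mean(total) == pytest.approx(np.mean(var), rel=0.10)

    def test_dc_offset_invariance(self):
        es = _noise_es(seed=4)
        shifted = _es(es.epochs + 17.0)
        np.testing.assert_allclose(psd_features(es).matrix,
                                   psd_features(shifted).matrix,
                                   rtol=1e-8, atol=1e-12)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            psd_features(_noise_es(), FeatureConfig(psd_band_hz=(0.001, 0.002)))


class TestDwt:
    def test_printed_dims_dimensionality(self):
        """31 kept approximation coefficients x 11 channels = 341."""
        fm = dwt_features(_noise_es())
        assert fm.n_features == 341
        assert fm.meta["native_coeff_count"] == 33

    def test_natural_profile_reports_true_count(self):
        fm = dwt_features(_noise_es(), FeatureConfig.natural())
        assert fm.n_features == 33 * N_CH

    def test_coefficient_count_formula_vs_bruteforce(self):
        """The iterated length formula floor((n+15)/2) and the fast path
        agree with a brute-force pad/convolve/decimate oracle."""
        f = wavelets.db_filters(8)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(165)
        n = 165
        for _ in range(3):
            n = (n + 15) // 2
        assert n == 33

        def brute_dwt(sig, filt):
            padded = np.concatenate([sig[:15][::-1], sig, sig[-15:][::-1]])
            out = []
            for k in range(1, len(padded) - 15, 2):
                acc = 0.0
                for m in range(16):
                    acc += padded[k + 15 - m] * filt[m]
                out.append(acc)
            return np.array(out)

        approx = x
        for _ in range(3):
            approx = brute_dwt(approx, np.asarray(f.dec_lo))
        fast = wavelets.wavedec(x, 3)[0]
        assert len(approx) == len(fast) == 33
        np.testing.assert_allclose(fast, approx, rtol=1e-10, atol=1e-10)

    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(165)
        coeffs = wavelets.wavedec(x, 3)
        back = wavelets.waverec(coeffs, 165)
        assert np.max(np.abs(back - x)) < 1e-8 * np.max(np.abs(x))

    def test_constant_signal_details_vanish(self):
        """db8 has 8 vanishing moments: a constant lives entirely in the
        approximation branch (periodic boundary)."""
        x = np.full(164, 2.5)
        cA, cD = wavelets.dwt(x, mode="periodization")
        assert np.max(np.abs(cD)) < 1e-8 * np.max(np.abs(cA))
        np.testing.assert_allclose(cA, 2.5 * np.sqrt(2.0), rtol=1e-10)

    def test_filter_matches_published_db8(self):
        h = wavelets.daubechies_filter(8)
        assert len(h) == 16
        assert h[0] == pytest.approx(0.05441584224308161, abs=1e-10)
        assert h[-1] == pytest.approx(-0.00011747678400228192, abs=1e-10)
        assert np.sum(h) == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert np.sum(h**2) == pytest.approx(1.0, abs=1e-12)

    def test_too_short_signal_rejected(self):
        es = _es(np.zeros((2, N_CH, 375)))
        with pytest.raises(ValueError, match="too short"):
            dwt_features(es, FeatureConfig(dwt_level=6, dwt_keep=None))


class TestNormalizer:
    def test_train_extrema_map_to_unit_interval(self):
        fm = FeatureMatrix(matrix=np.array([[0.0], [5.0], [10.0]]),
                           names=["f0"], labels=["control"] * 3)
        bounds = fit_normalizer(fm)
        out = apply_normalizer(bounds, fm)
        np.testing.assert_allclose(out.matrix[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        fm = FeatureMatrix(matrix=np.full((4, 1), 9.0), names=["f0"],
                           labels=["control"] * 4)
        out = apply_normalizer(fit_normalizer(fm), fm)
        np.testing.assert_allclose(out.matrix, 0.0)

    def test_out_of_range_test_values_allowed(self):
        train = FeatureMatrix(matrix=np.array([[0.0], [5.0], [10.0]]),
                              names=["f0"], labels=["control"] * 3)
        test = FeatureMatrix(matrix=np.array([[12.0]]), names=["f0"],
                             labels=["explosion"])
        out = apply_normalizer(fit_normalizer(train), test)
        assert out.matrix[0, 0] == pytest.approx(1.4)

    def test_name_mismatch_rejected(self):
        train = FeatureMatrix(matrix=np.zeros((2, 1)), names=["f0"],
                              labels=["control"] * 2)
        other = FeatureMatrix(matrix=np.zeros((2, 1)), names=["g0"],
                              labels=["control"] * 2)
        with pytest.raises(ValueError, match="names"):
            apply_normalizer(fit_normalizer(train), other)


class TestFusion:
    def test_printed_dims_fused_width(self):
        """VAR(44) + PSD(275) + DWT(341) concatenate to 660 columns."""
        es = _noise_es(n_trials=4, seed=7)
        fused = fuse([var_features(es), psd_features(es), dwt_features(es)])
        assert fused.n_features == 660

    def test_single_matrix_identity(self):
        fm = var_features(_noise_es(n_trials=3, seed=8))
        out = fuse([fm])
        np.testing.assert_array_equal(out.matrix, fm.matrix)
        assert out.names == fm.names

    def test_width_conservation(self):
        es = _noise_es(n_trials=3, seed=9)
        parts = [var_features(es), psd_features(es)]
        fused = fuse(parts)
        assert fused.n_features == sum(p.n_features for p in parts)

    def test_row_mismatch_rejected(self):
        a = var_features(_noise_es(n_trials=3, seed=10))
        b = var_features(_noise_es(n_trials=4, seed=10))
        with pytest.raises(ValueError, match="trials"):
            fuse([a, b])


class TestDeterminismAndProvenance:
    def test_identical_epochs_identical_features(self):
        es = _noise_es(seed=11)
        for extractor in (var_features, psd_features, dwt_features):
            np.testing.assert_array_equal(extractor(es).matrix,
                                          extractor(es).matrix)

    def test_channel_permutation_permutes_columns(self):
        es = _noise_es(n_trials=3, seed=12)
        perm = list(FEATURE_CHANNELS[::-1])
        cfg_fwd = FeatureConfig()
        cfg_rev = FeatureConfig(channels=tuple(perm))
        fwd = var_features(es, cfg_fwd)
        rev = var_features(es, cfg_rev)
        # same named feature -> same value, regardless of channel order
        lookup = dict(zip(fwd.names, fwd.matrix.T))
        for name, col in zip(rev.names, rev.matrix.T):
            np.testing.assert_allclose(col, lookup[name], rtol=1e-12)
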