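"""Filtering, epoching, baseline, artifact handling and averaging."""

import numpy as np
import pytest

from oddball_eeg.montage import CHANNELS, FEATURE_CHANNELS
from oddball_eeg.preprocess import (FilterSpec, apply_filters,
                                    baseline_correct, exclude_channels,
                                    grand_average, reject_trials,
                                    remove_ocular_artifacts, segment_epochs,
                                    subject_average)
from oddball_eeg.simulate import ContinuousRecording

FS = 250.0


def _rec(data, events=None, channels=None):
    chans = channels or CHANNELS[:data.shape[0]]
    return ContinuousRecording(channel_names=list(chans), sampling_rate=FS,
                               data=data, events=events or [])


def _sine(freq, n=8000, amp=1.0):
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilters:
    def test_notch_kills_line_frequency(self):
        """A pure 50 Hz sinusoid is attenuated by >= 20 dB."""
        rec = _rec(_sine(50.0)[None, :], channels=["O2"])
        out = apply_filters(rec)
        core = slice(1000, -1000)  # avoid edge transients
        assert np.sqrt(np.mean(out.data[0, core] ** 2)) <= \
            0.1 * np.sqrt(np.mean(rec.data[0, core] ** 2))

    def test_passband_gain_near_unity(self):
        rec = _rec(_sine(10.0)[None, :], channels=["O2"])
        out = apply_filters(rec)
        core = slice(1000, -1000)
        ratio = np.sqrt(np.mean(out.data[0, core] ** 2)) \
            / np.sqrt(np.mean(rec.data[0, core] ** 2))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_dc_removed_by_highpass(self):
        rec = _rec(np.full((1, 8000), 5.0), channels=["O2"])
        out = apply_filters(rec)
        assert np.abs(out.data[0, 1000:-1000]).max() < 0.1 * 5.0

    def test_zero_phase_peak_not_shifted(self):
        """A 10 Hz sinusoid's peak sample index is unchanged (+-1)."""
        x = _sine(10.0)
        rec = _rec(x[None, :], channels=["O2"])
        out = apply_filters(rec)
        seg = slice(4000, 4000 + 25)  # one period
        assert abs(int(np.argmax(out.data[0, seg]))
                   - int(np.argmax(x[seg]))) <= 1

    def test_too_short_recording_rejected(self):
        rec = _rec(np.zeros((1, 100)), channels=["O2"])
        with pytest.raises(ValueError, match="shorter than"):
            apply_filters(rec)

    def test_invalid_band_rejected(self):
        rec = _rec(np.zeros((1, 8000)), channels=["O2"])
        with pytest.raises(ValueError):
            apply_filters(rec, FilterSpec(bp_low_hz=50.0, bp_high_hz=40.0))


class TestSegmentation:
    def test_session_epoch_count_and_length(self):
        """240 interior events of a -0.5..+1.0 s window at 250 Hz give 240
        epochs of 375 samples (half-open convention)."""
        n = 240 * 400 + 1000
        events = [(500 + 400 * i, "control") for i in range(240)]
        es = segment_epochs(_rec(np.zeros((4, n)), events))
        assert es.epochs.shape == (240, 4, 375)
        assert es.onset_index == 125

    def test_edge_event_skipped_and_logged(self):
        events = [(10, "control"), (2000, "explosion")]
        es = segment_epochs(_rec(np.zeros((2, 4000)), events))
        assert es.n_trials == 1
        assert len(es.skipped_events) == 1
        assert es.skipped_events[0][0] == 10

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="no event"):
            segment_epochs(_rec(np.zeros((2, 4000)), []))

    def test_epoch_conservation(self):
        """epochs + skipped = events."""
        events = [(10, "control"), (1000, "control"), (3990, "burning")]
        es = segment_epochs(_rec(np.zeros((2, 4000)), events))
        assert es.n_trials + len(es.skipped_events) == len(events)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self, epochset_factory):
        es = epochset_factory(np.full((3, 2, 375), 7.0), ["control"] * 3)
        out = baseline_correct(es)
        np.testing.assert_allclose(out.epochs, 0.0, atol=1e-12)

    def test_pre_onset_mean_is_zero(self, epochset_factory):
        rng = np.random.default_rng(1)
        es = epochset_factory(rng.standard_normal((5, 3, 375)),
                              ["explosion"] * 5)
        out = baseline_correct(es)
        pre = out.epochs[:, :, :out.onset_index].mean(axis=2)
        assert np.abs(pre).max() < 1e-9

    def test_shape_preserving_and_idempotent(self, epochset_factory):
        rng = np.random.default_rng(2)
        es = epochset_factory(rng.standard_normal((4, 2, 375)),
                              ["burning"] * 4)
        once = baseline_correct(es)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.epochs, twice.epochs, atol=1e-12)
        # post-onset waveform shape preserved up to the subtracted scalar
        diff = es.epochs - once.epochs
        assert np.ptp(diff, axis=2).max() < 1e-12


class TestOcularRemoval:
    @staticmethod
    def _blinky_data(seed=0, n=20000):
        rng = np.random.default_rng(seed)
        neural = rng.standard_normal((len(CHANNELS), n))
        blink = np.zeros(n)
        kernel = np.exp(-np.linspace(-3, 3, 101) ** 2)
        for c in range(500, n - 200, 900):
            blink[c:c + 101] += 40 * kernel
        weights = np.array([1.0 if ch in ("Fp1", "Fp2") else
                            0.3 if ch.startswith("F") else 0.02
                            for ch in CHANNELS])
        return neural + np.outer(weights, blink), blink

    @pytest.mark.parametrize("method", ["regression", "ica_corr"])
    def test_injected_blinks_removed(self, method):
        data, blink = self._blinky_data()
        cleaned, report = remove_ocular_artifacts((data, list(CHANNELS)),
                                                  method=method, seed=0)
        for row in cleaned:
            r = np.corrcoef(row, blink)[0, 1]
            assert abs(r) < 0.2

    def test_blink_free_data_nearly_untouched(self):
        """Without blinks the regression is a near no-op on all channels
        except the ocular proxies themselves (which always share the
        regressor by construction)."""
        rng = np.random.default_rng(3)
        data = rng.standard_normal((len(CHANNELS), 10000))
        cleaned, _ = remove_ocular_artifacts((data, list(CHANNELS)),
                                             method="regression")
        rms_diff = np.sqrt(np.mean((cleaned - data) ** 2, axis=1))
        rms = np.sqrt(np.mean(data ** 2, axis=1))
        keep = [i for i, ch in enumerate(CHANNELS) if ch not in ("Fp1", "Fp2")]
        assert np.all(rms_diff[keep] < 0.05 * rms[keep])

    def test_ica_component_selection_deterministic(self):
        """The same seed reproduces the same decomposition, component
        selection and cleaned signal (including any logged fallback)."""
        data, _ = self._blinky_data(seed=4)
        out1, rep1 = remove_ocular_artifacts((data, list(CHANNELS)),
                                             method="ica_corr", seed=11)
        out2, rep2 = remove_ocular_artifacts((data, list(CHANNELS)),
                                             method="ica_corr", seed=11)
        assert rep1 == rep2
        np.testing.assert_array_equal(out1, out2)

    def test_missing_proxy_channels_rejected(self):
        data = np.zeros((2, 1000))
        with pytest.raises(ValueError, match="proxy"):
            remove_ocular_artifacts((data, ["O1", "O2"]), method="regression")


class TestTrialRejection:
    @staticmethod
    def _homogeneous(n=100, seed=0):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, len(FEATURE_CHANNELS), 375))

    def test_infinite_thresholds_keep_everything(self, epochset_factory):
        es = epochset_factory(self._homogeneous(), ["control"] * 100,
                              channel_names=list(FEATURE_CHANNELS))
        out = reject_trials(es, z_var=np.inf, z_kurt=np.inf)
        assert out.kept.all()

    def test_high_variance_outlier_detected(self, epochset_factory):
        data = self._homogeneous(seed=1)  # ensemble clean at z=3 on its own
        data[17] *= 100.0
        es = epochset_factory(data, ["control"] * 100,
                              channel_names=list(FEATURE_CHANNELS))
        out = reject_trials(es, z_var=3.0, z_kurt=np.inf)
        assert list(np.where(~out.kept)[0]) == [17]
        assert "variance" in out.reject_reasons[17]

    def test_spike_detected_via_kurtosis(self, epochset_factory):
        data = self._homogeneous()
        data[42, :, 180] += 30.0  # single huge spike, modest variance
        es = epochset_factory(data, ["control"] * 100,
                              channel_names=list(FEATURE_CHANNELS))
        out = reject_trials(es, z_var=np.inf, z_kurt=3.0)
        assert list(np.where(~out.kept)[0]) == [42]
        assert "kurtosis" in out.reject_reasons[42]

    def test_all_rejected_is_an_error(self, epochset_factory):
        es = epochset_factory(self._homogeneous(6), ["control"] * 6,
                              channel_names=list(FEATURE_CHANNELS))
        with pytest.raises(ValueError, match="all epochs rejected"):
            reject_trials(es, z_var=-10.0, z_kurt=-10.0,
                          group_by_condition=False)


class TestAveraging:
    def test_subject_average_manifest_and_mean(self, epochset_factory):
        rng = np.random.default_rng(5)
        es = epochset_factory(rng.standard_normal((50, 2, 375)),
                              ["control"] * 50)
        avg, manifest = subject_average(es, "control", n_select=38, seed=0)
        assert len(manifest) == 38
        np.testing.assert_allclose(avg, es.epochs[manifest].mean(axis=0))

    def test_average_of_identical_epochs_is_the_epoch(self, epochset_factory):
        one = np.random.default_rng(6).standard_normal((1, 2, 375))
        es = epochset_factory(np.repeat(one, 40, axis=0), ["explosion"] * 40)
        avg, _ = subject_average(es, "explosion", n_select=38, seed=1)
        np.testing.assert_allclose(avg, one[0])

    def test_shortfall_is_explicit(self, epochset_factory):
        es = epochset_factory(np.zeros((10, 2, 375)), ["explosion"] * 10)
        with pytest.raises(ValueError, match="shortfall"):
            subject_average(es, "explosion", n_select=38)

    def test_grand_average_closed_form(self):
        plus = {"control": np.ones((2, 375))}
        minus = {"control": -np.ones((2, 375))}
        ga = grand_average([plus, minus], ["O2", "Pz"], FS)
        np.testing.assert_allclose(ga.means["control"], 0.0)
        np.testing.assert_allclose(ga.sds["control"], np.sqrt(2.0))

    def test_identical_subjects_have_zero_sd(self):
        avg = {"control": np.random.default_rng(7).standard_normal((2, 375))}
        ga = grand_average([avg, dict(avg)], ["O2", "Pz"], FS)
        np.testing.assert_allclose(ga.sds["control"], 0.0, atol=1e-12)

    def test_mismatched_channels_rejected(self):
        with pytest.raises(ValueError):
            grand_average([{"control": np.zeros((2, 375))},
                           {"control": np.zeros((3, 375))}], ["O2", "Pz"], FS)

    def test_noise_reduction_scales_as_inverse_sqrt_n(self):
        """Averaging n white-noise epochs shrinks the residual SD like
        n^-1/2 (fitted exponent within [0.4, 0.6])."""
        rng = np.random.default_rng(8)
        pool = rng.standard_normal((256, 375))
        ns = np.array([4, 16, 64, 256])
        sds = np.array([pool[:n].mean(axis=0).std() for n in ns])
        slope = np.polyfit(np.log(ns), np.log(sds), 1)[0]
        assert -0.6 <= slope <= -0.4


def test_exclude_channels_default_profile(small_noisy_session):
    out = exclude_channels(small_noisy_session)
    assert "O1" not in out.channel_names and "PO7" not in out.channel_names
    assert len(out.channel_names) == 22
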