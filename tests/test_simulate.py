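"""Session schedule, evoked templates and recording synthesis."""

import numpy as np
import pytest
from scipy import stats as spstats

from oddball_eeg.montage import CHANNELS
from oddball_eeg.presets import study_presets, preset
from oddball_eeg.simulate import (NoiseConfig, SessionConfig, SubjectProfile,
                                  build_schedule, evoked_waveform,
                                  synthesize_recording)


class TestSchedule:
    def test_study_counts(self, study_session_cfg):
        sched = build_schedule(study_session_cfg, seed=0)
        assert sched.counts() == {"explosion": 40, "burning": 40,
                                  "control": 160}

    def test_zero_deviant_fraction_all_control(self, study_session_cfg):
        cfg = SessionConfig(deviant_fraction=0.0)
        sched = build_schedule(cfg, seed=0)
        assert sched.counts() == {"explosion": 0, "burning": 0, "control": 240}

    def test_determinism(self, study_session_cfg):
        a = build_schedule(study_session_cfg, seed=7)
        b = build_schedule(study_session_cfg, seed=7)
        assert a.labels == b.labels
        np.testing.assert_array_equal(a.onsets_s, b.onsets_s)

    def test_unsplittable_deviant_count_rejected(self):
        # 0.17 * 240 rounds to 41 deviants — cannot split equally
        cfg = SessionConfig(deviant_fraction=0.17)
        with pytest.raises(ValueError, match="split equally"):
            build_schedule(cfg, seed=0)

    def test_onsets_respect_duration_and_gaps(self, study_session_cfg):
        cfg = study_session_cfg
        sched = build_schedule(cfg, seed=3)
        starts = sched.trial_starts_s
        assert np.all(np.diff(sched.onsets_s) > 0)
        gaps = np.diff(starts) - cfg.trial_duration_s
        lo, hi = cfg.inter_trial_gap_s
        assert gaps.min() >= lo - 1e-9 and gaps.max() <= hi + 1e-9
        np.testing.assert_allclose(sched.onsets_s - starts,
                                   cfg.stimulus_delay_s)

    def test_order_randomization_uniform_positions(self):
        """Deviant positions over many seeds are uniform across trial
        slots (chi-square sanity check)."""
        cfg = SessionConfig(n_blocks=1, trials_per_block=24)
        counts = np.zeros(24)
        n_seeds = 300
        for seed in range(n_seeds):
            labels = np.array(build_schedule(cfg, seed=seed).labels)
            counts += labels == "explosion"
        expected = counts.sum() / 24
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert spstats.chi2.sf(chi2, df=23) > 1e-3


class TestEvokedWaveform:
    t = np.arange(0, 300) / 250.0  # 0..1.2 s

    def test_control_is_zero(self, clean_profile):
        out = evoked_waveform(preset("control", "visual_only"),
                              clean_profile, self.t)
        assert not out.any()

    def test_explosion_p1_amplitude_at_o2(self, clean_profile):
        """The visual-only explosion template carries +11.5 a.u. at O2 at
        its 125 ms peak."""
        out = evoked_waveform(preset("explosion", "visual_only"),
                              clean_profile, self.t)
        i_o2 = CHANNELS.index("O2")
        i_peak = int(round(0.125 * 250))
        assert out[i_o2, i_peak] == pytest.approx(11.5, rel=0.01)

    def test_amplitude_scales_with_profile(self, clean_profile):
        from dataclasses import replace
        prof2 = replace(clean_profile, amplitude_scale=2.0)
        a = evoked_waveform(preset("explosion", "visual_only"),
                            clean_profile, self.t)
        b = evoked_waveform(preset("explosion", "visual_only"), prof2, self.t)
        np.testing.assert_allclose(b, 2.0 * a)

    def test_zero_weight_channel_contributes_nothing(self, clean_profile):
        from dataclasses import replace as drep
        from oddball_eeg.simulate import ComponentTemplate, ConditionPreset
        topo = {ch: 0.0 for ch in CHANNELS}
        topo["O2"] = 1.0
        comp = ComponentTemplate(name="P1", polarity=1, peak_amplitude=5.0,
                                 peak_latency_ms=100.0, width_ms=30.0,
                                 topography=topo)
        p = ConditionPreset(condition="explosion", modality="visual_only",
                            components=(comp,))
        out = evoked_waveform(p, clean_profile, self.t)
        for i, ch in enumerate(CHANNELS):
            if ch != "O2":
                assert not out[i].any()

    def test_latency_outside_grid_rejected(self, clean_profile):
        short_grid = np.arange(0, 20) / 250.0  # 80 ms
        with pytest.raises(ValueError, match="outside"):
            evoked_waveform(preset("explosion", "visual_only"),
                            clean_profile, short_grid)


class TestSynthesizeRecording:
    def test_noise_free_window_equals_template(self, small_session_cfg,
                                               clean_profile, visual_presets):
        sched = build_schedule(small_session_cfg, seed=5)
        rec = synthesize_recording(sched, visual_presets, clean_profile,
                                   noise=NoiseConfig.silent(), seed=5)
        n_win = int(1.2 * 250)
        local_t = np.arange(n_win) / 250.0
        for onset, cond in rec.events[:10]:
            expected = evoked_waveform(visual_presets[cond], clean_profile,
                                       local_t)
            np.testing.assert_allclose(rec.data[:, onset:onset + n_win],
                                       expected, atol=1e-12)

    def test_event_list_matches_schedule(self, small_session_cfg,
                                         clean_profile, visual_presets):
        sched = build_schedule(small_session_cfg, seed=5)
        rec = synthesize_recording(sched, visual_presets, clean_profile,
                                   noise=NoiseConfig.silent(), seed=5)
        assert [c for _, c in rec.events] == list(sched.labels)

    def test_reproducible_with_seed(self, small_session_cfg, unit_profile,
                                    visual_presets):
        sched = build_schedule(small_session_cfg, seed=1)
        a = synthesize_recording(sched, visual_presets, unit_profile, seed=9)
        b = synthesize_recording(sched, visual_presets, unit_profile, seed=9)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.events == b.events

    def test_control_epoch_average_near_zero(self, small_noisy_session):
        """Monte-Carlo convergence: the mean of many control epochs at O2
        stays within 3 empirical standard errors of zero."""
        rec = small_noisy_session
        i_o2 = rec.channel_names.index("O2")
        onsets = [s for s, c in rec.events if c == "control"]
        assert len(onsets) >= 40
        wins = np.stack([rec.data[i_o2, s:s + 200] for s in onsets])
        wins = wins - wins.mean(axis=1, keepdims=True)  # drift offsets
        mean = wins.mean(axis=0)
        se = wins.std(axis=0, ddof=1) / np.sqrt(len(onsets))
        assert np.all(np.abs(mean) <= 3.5 * se + 1e-9)

    def test_stimulus_average_recovers_p1(self, small_noisy_session,
                                          small_session_cfg):
        """Law of large numbers: the 40-trial explosion average at O2
        recovers the injected P1 amplitude within 3 SE."""
        rec = small_noisy_session
        fs = rec.sampling_rate
        i_o2 = rec.channel_names.index("O2")
        onsets = [s for s, c in rec.events if c == "explosion"]
        assert len(onsets) == 40
        pre = int(0.3 * fs)
        wins = np.stack([rec.data[i_o2, s - pre:s + 250] for s in onsets])
        wins = wins - wins[:, :pre].mean(axis=1, keepdims=True)
        i_peak = pre + int(round(0.125 * fs))
        vals = wins[:, i_peak]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 11.5) <= 3 * se


class TestPresetStructure:
    @pytest.mark.parametrize("modality", ["visual_only", "audio_visual"])
    def test_presets_validate(self, modality):
        presets = study_presets(modality)
        assert set(presets) == {"explosion", "burning", "control"}
        assert presets["control"].components == ()

    def test_av_burning_erp_larger_than_visual_only(self):
        """Sound enhances the burning-box ERP complex (N2c, P3b) and
        suppresses the P1 — the modality effect the generator encodes."""
        vo = {c.name: c for c in preset("burning", "visual_only").components}
        av = {c.name: c for c in preset("burning", "audio_visual").components}
        assert av["N2c"].peak_amplitude > vo["N2c"].peak_amplitude
        assert av["P3b"].peak_amplitude > vo["P3b"].peak_amplitude
        assert av["P1"].peak_amplitude < vo["P1"].peak_amplitude
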