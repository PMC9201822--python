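"""Cohort-level experiments: parameter recovery and event detection.

These helpers chain the library end to end the way the analysis drivers
do — simulate a cohort of subjects, preprocess each session (channel
exclusion, notch + band-pass, epoching, baseline, trial rejection),
average, and either measure ERP peaks on the grand average or extract
single-trial features and run the SVM detection protocol.  Subjects are
processed one at a time so a full 8-subject session cohort stays within
desk-scale memory.

Ocular-artifact removal is deliberately not part of this default chain:
blinks live on the frontal-polar channels, which enter neither the
feature set nor the O2/Pz peak measures, and the rejection step handles
the rare epochs they leak into.  The `pipeline` module exposes it as an
optional stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classify import CVConfig, FoldMetrics, assemble_dataset, crossval_train_eval
from .features import FeatureConfig, FeatureMatrix, extract_all, fuse
from .montage import DEFAULT_EXCLUDED
from .preprocess import (EpochSet, FilterSpec, GrandAverage, apply_filters,
                         baseline_correct, exclude_channels, grand_average,
                         reject_trials, segment_epochs, subject_average)
from .presets import study_presets
from .simulate import (ContinuousRecording, NoiseConfig, SessionConfig,
                       SubjectProfile, as_seed_sequence, draw_subject_profiles,
                       simulate_session)

__all__ = ["CohortSpec", "preprocess_recording", "subset_epochs",
           "recovery_cohort", "detection_runs", "METHODS"]

METHODS = ("VAR", "PSD", "DWT", "DVP")


@dataclass(frozen=True)
class CohortSpec:
    """What to simulate for one cohort of subjects."""

    modality: str = "visual_only"
    n_subjects: int = 8
    n_select: int = 38
    session: SessionConfig = SessionConfig()
    noise: NoiseConfig = NoiseConfig()
    filter_spec: FilterSpec = FilterSpec()
    exclude: tuple[str, ...] = DEFAULT_EXCLUDED
    z_var: float = 3.0
    z_kurt: float = 3.0
    amplitude_scale_sd: float = 0.15
    latency_shift_sd_ms: float = 6.0
    noise_level: float = 10.0
    blink_rate_per_min: float = 12.0


def preprocess_recording(rec: ContinuousRecording,
                         filter_spec: FilterSpec | None = None,
                         exclude: tuple[str, ...] = DEFAULT_EXCLUDED,
                         window_s: tuple[float, float] = (-0.5, 1.0),
                         z_var: float = 3.0, z_kurt: float = 3.0,
                         subject_id: str = "") -> EpochSet:
    """Standard per-subject chain: exclusion, filters, epochs, baseline,
    ensemble trial rejection."""
    rec = exclude_channels(rec, exclude)
    rec = apply_filters(rec, filter_spec)
    es = segment_epochs(rec, window_s=window_s, subject_id=subject_id)
    es = baseline_correct(es)
    return reject_trials(es, z_var=z_var, z_kurt=z_kurt)


def subset_epochs(es: EpochSet, indices: list[int]) -> EpochSet:
    """Epoch set restricted to the given trial indices (all marked kept)."""
    return replace(
        es,
        epochs=es.epochs[indices],
        labels=[es.labels[i] for i in indices],
        kept=np.ones(len(indices), dtype=bool),
        reject_reasons=[es.reject_reasons[i] for i in indices],
    )


def _usable_subjects(spec: CohortSpec, seed):
    """Yield ``n_subjects`` preprocessed sessions with at least
    ``n_select`` kept trials in every condition.

    A simulated subject whose rejection leaves a shortfall in any
    condition is excluded and replaced by a freshly drawn one — the
    synthetic analogue of subject exclusion in real cohorts (the mirrored
    study likewise dropped subjects and fixed the per-subject trial count
    at 38).  At most ``3 * n_subjects`` draws are attempted.

    Yields ``(profile, epoch_set, selection_seed)`` tuples.
    """
    import logging
    log = logging.getLogger(__name__)
    presets = study_presets(spec.modality)
    ss = as_seed_sequence(seed)
    attempts = ss.spawn(3 * spec.n_subjects)
    n_ok = 0
    for k, s_attempt in enumerate(attempts):
        if n_ok == spec.n_subjects:
            return
        s_prof, s_sim, s_sel = s_attempt.spawn(3)
        profile = draw_subject_profiles(
            1, seed=s_prof,
            amplitude_scale_sd=spec.amplitude_scale_sd,
            latency_shift_sd_ms=spec.latency_shift_sd_ms,
            noise_level=spec.noise_level,
            blink_rate_per_min=spec.blink_rate_per_min)[0]
        profile = replace(profile, subject_id=f"S{k + 1:02d}")
        rec = simulate_session(spec.session, presets, profile,
                               seed=s_sim, noise=spec.noise)
        es = preprocess_recording(rec, spec.filter_spec, spec.exclude,
                                  z_var=spec.z_var, z_kurt=spec.z_kurt,
                                  subject_id=profile.subject_id)
        kept = np.asarray(es.kept)
        labels = np.asarray(es.labels)
        short = [c for c in sorted(set(es.labels))
                 if (kept & (labels == c)).sum() < spec.n_select]
        if short:
            log.warning("subject %s excluded: fewer than %d kept trials in %s",
                        profile.subject_id, spec.n_select, short)
            continue
        n_ok += 1
        yield profile, es, s_sel
    if n_ok < spec.n_subjects:
        raise RuntimeError(
            f"could not assemble {spec.n_subjects} usable subjects in "
            f"{len(attempts)} draws; rejection thresholds may be too strict")


def recovery_cohort(spec: CohortSpec, seed: int | None = 0) -> GrandAverage:
    """Simulate, preprocess and grand-average one cohort.

    Returns the across-subject grand average built from ``n_select``
    trials per condition per subject (seeded random selection), i.e. the
    input to ERP peak recovery.
    """
    subject_avgs = []
    channel_names = None
    for profile, es, s_sel in _usable_subjects(spec, seed):
        avgs = {}
        conds = sorted(set(es.labels))
        for cond, s_cond in zip(conds, s_sel.spawn(len(conds))):
            avgs[cond], _ = subject_average(es, cond, n_select=spec.n_select,
                                            seed=s_cond)
        subject_avgs.append(avgs)
        channel_names = es.channel_names
        fs, window = es.sampling_rate, es.window_s
    return grand_average(subject_avgs, channel_names, fs, window,
                         trials_per_subject=spec.n_select)


def _pooled_method_features(spec: CohortSpec, feature_cfg: FeatureConfig,
                            condition: str, seed) -> dict[str, dict[str, FeatureMatrix]]:
    """Per-method pooled stimulus/control feature matrices for a cohort."""
    pooled: dict[str, dict[str, list[FeatureMatrix]]] = {
        m: {"stim": [], "ctrl": []} for m in METHODS}
    for profile, es, s_sel in _usable_subjects(spec, seed):
        s_stim, s_ctrl = s_sel.spawn(2)
        _, stim_idx = subject_average(es, condition, n_select=spec.n_select,
                                      seed=s_stim)
        _, ctrl_idx = subject_average(es, "control", n_select=spec.n_select,
                                      seed=s_ctrl)
        for role, idx in (("stim", stim_idx), ("ctrl", ctrl_idx)):
            mats = extract_all(subset_epochs(es, idx), feature_cfg)
            for m in METHODS:
                pooled[m][role].append(mats[m])
    out: dict[str, dict[str, FeatureMatrix]] = {}
    for m in METHODS:
        out[m] = {}
        for role in ("stim", "ctrl"):
            parts = pooled[m][role]
            out[m][role] = FeatureMatrix(
                matrix=np.vstack([p.matrix for p in parts]),
                names=list(parts[0].names),
                labels=[lb for p in parts for lb in p.labels],
                meta=dict(parts[0].meta))
    return out


def detection_runs(conditions: tuple[str, ...] = ("explosion", "burning"),
                   modalities: tuple[str, ...] = ("visual_only", "audio_visual"),
                   spec: CohortSpec | None = None,
                   feature_cfg: FeatureConfig | None = None,
                   cv: CVConfig | None = None,
                   seed: int | None = 0
                   ) -> dict[tuple[str, str, str], list[FoldMetrics]]:
    """Fold metrics for every (method, condition, modality) combination,
    the input to :func:`oddball_eeg.classify.build_report`.

    The same simulated cohort (per modality) serves both conditions, as
    in the original protocol where one session contains all three trial
    types.
    """
    feature_cfg = feature_cfg or FeatureConfig()
    cv = cv or CVConfig()
    base = spec or CohortSpec()
    runs: dict[tuple[str, str, str], list[FoldMetrics]] = {}
    ss = as_seed_sequence(seed)
    for modality, s_mod in zip(modalities, ss.spawn(len(modalities))):
        mod_spec = replace(base, modality=modality)
        for cond, s_cond in zip(conditions, s_mod.spawn(len(conditions))):
            feats = _pooled_method_features(mod_spec, feature_cfg, cond, s_cond)
            for m in METHODS:
                X, y, _ = assemble_dataset(feats[m]["stim"], feats[m]["ctrl"],
                                           balance=True, seed=cv.seed)
                runs[(m, cond, modality)] = crossval_train_eval(
                    X, y, cv, names=feats[m]["stim"].names)
    return runs
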