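"""Configuration, stage orchestration and provenance.

A :class:`RunConfig` (YAML-loadable, schema-validated, unknown keys
rejected) drives the staged chain

    simulate -> preprocess -> erp -> features -> classify -> report

Every stage writes its artifacts plus a ``<stage>_manifest.json``
recording the configuration hash, the master seed, input-file hashes and
the package version, so any output is traceable.  Deterministic stages
re-run byte-stable under an identical configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .classify import CVConfig, FoldMetrics, assemble_dataset, build_report, crossval_train_eval
from .edfio import read_session, write_session
from .erp import (DEFAULT_SEARCH_WINDOWS_MS, peak_from_grand_average,
                  scalp_snapshot)
from .experiments import METHODS, subset_epochs
from .features import FeatureConfig, FeatureMatrix, extract_all
from .montage import DEFAULT_EXCLUDED
from .preprocess import (FilterSpec, apply_filters, baseline_correct,
                         exclude_channels, grand_average,
                         remove_ocular_artifacts, reject_trials,
                         segment_epochs, subject_average)
from .presets import study_presets
from .simulate import (NoiseConfig, SessionConfig, as_seed_sequence,
                       draw_subject_profiles, simulate_session)
from .store import (load_epochs, load_features, load_grand_average,
                    save_epochs, save_features, save_grand_average)

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "erp", "features", "classify", "report")

__all__ = ["RunConfig", "run_stage", "run_all", "STAGES"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SessionBlock(_Block):
    n_blocks: int = 8
    trials_per_block: int = 30
    trial_duration_s: float = 6.0
    deviant_fraction: float = 1.0 / 3.0
    sampling_rate: float = 250.0
    inter_trial_gap_s: tuple[float, float] = (1.3, 2.0)
    stimulus_delay_s: float = 2.0

    def to_config(self) -> SessionConfig:
        return SessionConfig(**self.model_dump())


class CohortBlock(_Block):
    modalities: tuple[str, ...] = ("visual_only", "audio_visual")
    n_subjects: int = 8
    #: extra recorded-then-maybe-excluded subjects, mirroring the 9-of-8
    #: recruitment margin of real cohorts
    n_spare_subjects: int = 1
    n_select: int = 38
    amplitude_scale_sd: float = 0.15
    latency_shift_sd_ms: float = 6.0
    noise_level: float = 10.0
    blink_rate_per_min: float = 12.0


class NoiseBlock(_Block):
    alpha_rms: float = 4.0
    line_amps: tuple[float, float] = (4.0, 1.5)
    drift_rms: float = 15.0
    blink_amplitude: float = 60.0
    modulation_sd: float = 0.10

    def to_config(self) -> NoiseConfig:
        return NoiseConfig(**self.model_dump())


class FilterBlock(_Block):
    notch_freqs_hz: tuple[float, ...] = (50.0, 100.0)
    notch_q: float = 30.0
    bp_low_hz: float = 0.5
    bp_high_hz: float = 40.0
    fir_numtaps: int = 1651

    def to_spec(self) -> FilterSpec:
        return FilterSpec(**self.model_dump())


class RejectionBlock(_Block):
    z_var: float = 3.0
    z_kurt: float = 3.0
    group_by_condition: bool = True


class OcularBlock(_Block):
    enabled: bool = False
    method: str = "regression"      # or "ica_corr"
    corr_threshold: float = 0.8


class FeatureBlock(_Block):
    profile: str = "printed-dims"     # or "natural"

    def to_config(self) -> FeatureConfig:
        if self.profile == "printed-dims":
            return FeatureConfig()
        if self.profile == "natural":
            return FeatureConfig.natural()
        raise ValueError(f"unknown feature profile {self.profile!r}")


class CVBlock(_Block):
    k: int = 10
    test_fraction: float = 0.2
    scheme: str = "repeated_split"
    svm_c: float = 1.0

    def to_config(self, seed: int | None) -> CVConfig:
        return CVConfig(k=self.k, test_fraction=self.test_fraction,
                        scheme=self.scheme, svm_c=self.svm_c, seed=seed)


class RunConfig(_Block):
    """Validated top-level configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs/default"
    exclude_channels: tuple[str, ...] = DEFAULT_EXCLUDED
    epoch_window_s: tuple[float, float] = (-0.5, 1.0)
    session: SessionBlock = Field(default_factory=SessionBlock)
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    filters: FilterBlock = Field(default_factory=FilterBlock)
    rejection: RejectionBlock = Field(default_factory=RejectionBlock)
    ocular: OcularBlock = Field(default_factory=OcularBlock)
    features: FeatureBlock = Field(default_factory=FeatureBlock)
    cv: CVBlock = Field(default_factory=CVBlock)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# provenance helpers
# --------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(stage: str, cfg: RunConfig, out: Path,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "inputs": {p.name: _hash_file(p) for p in inputs},
        "outputs": {p.name: _hash_file(p) for p in outputs},
    }
    (out / f"{stage}_manifest.json").write_text(json.dumps(manifest, indent=2))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the {producer!r} stage first")
    return path


def _subject_seed(cfg: RunConfig, modality: str, i: int):
    mod_idx = cfg.cohort.modalities.index(modality)
    n = cfg.cohort.n_subjects + cfg.cohort.n_spare_subjects
    return as_seed_sequence(cfg.seed).spawn(len(cfg.cohort.modalities))[mod_idx] \
        .spawn(n + 1)[i]


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    session = cfg.session.to_config()
    noise = cfg.noise.to_config()
    outputs = []
    n_total = cfg.cohort.n_subjects + cfg.cohort.n_spare_subjects
    for modality in cfg.cohort.modalities:
        presets = study_presets(modality)
        s_prof = _subject_seed(cfg, modality, n_total)
        profiles = draw_subject_profiles(
            n_total, seed=s_prof,
            amplitude_scale_sd=cfg.cohort.amplitude_scale_sd,
            latency_shift_sd_ms=cfg.cohort.latency_shift_sd_ms,
            noise_level=cfg.cohort.noise_level,
            blink_rate_per_min=cfg.cohort.blink_rate_per_min)
        for i, profile in enumerate(profiles):
            rec = simulate_session(session, presets, profile,
                                   seed=_subject_seed(cfg, modality, i),
                                   noise=noise)
            edf = out / f"{modality}_{profile.subject_id}.edf"
            write_session(rec, edf)
            outputs += [edf, edf.with_name(edf.stem + "_events.tsv")]
            log.info("simulated %s", edf.name)
    return outputs


def _stage_preprocess(cfg: RunConfig, out: Path) -> list[Path]:
    outputs = []
    log_lines = ["modality\tsubject\ttrial\tlabel\tstatus\treason"]
    for modality in cfg.cohort.modalities:
        for edf in sorted(out.glob(f"{modality}_S*.edf")):
            _require(edf, "simulate")
            rec = read_session(edf)
            sid = edf.stem.split("_")[-1]
            rec = exclude_channels(rec, cfg.exclude_channels)
            rec = apply_filters(rec, cfg.filters.to_spec())
            if cfg.ocular.enabled:
                rec, _ = remove_ocular_artifacts(
                    rec, method=cfg.ocular.method,
                    corr_threshold=cfg.ocular.corr_threshold, seed=cfg.seed)
            es = segment_epochs(rec, window_s=cfg.epoch_window_s, subject_id=sid)
            es = baseline_correct(es)
            es = reject_trials(es, z_var=cfg.rejection.z_var,
                               z_kurt=cfg.rejection.z_kurt,
                               group_by_condition=cfg.rejection.group_by_condition)
            h5 = out / f"{modality}_{sid}_epochs.h5"
            save_epochs(es, h5)
            outputs.append(h5)
            for i, (lb, k, why) in enumerate(zip(es.labels, es.kept,
                                                 es.reject_reasons)):
                status = "kept" if k else "rejected"
                log_lines.append(f"{modality}\t{sid}\t{i}\t{lb}\t{status}\t{why}")
    rej = out / "rejection_log.tsv"
    rej.write_text("\n".join(log_lines) + "\n")
    outputs.append(rej)
    return outputs


def _subject_selection(cfg: RunConfig, es, s_sel):
    conds = sorted(set(es.labels))
    manifests = {}
    for cond, s_cond in zip(conds, s_sel.spawn(len(conds))):
        _, idx = subject_average(es, cond, n_select=cfg.cohort.n_select,
                                 seed=s_cond)
        manifests[cond] = idx
    return manifests


def _usable_epoch_sets(cfg: RunConfig, out: Path, modality: str):
    """Yield ``(epoch_set, selection)`` for up to ``n_subjects`` usable
    subjects, excluding any whose rejection left fewer than ``n_select``
    kept trials in some condition — the cohort was recorded with a spare
    subject for exactly this case."""
    files = sorted(out.glob(f"{modality}_S*_epochs.h5"))
    if not files:
        _require(out / f"{modality}_S01_epochs.h5", "preprocess")
    sel_seeds = as_seed_sequence(cfg.seed).spawn(len(files))
    n_ok = 0
    for f, s_sel in zip(files, sel_seeds):
        if n_ok == cfg.cohort.n_subjects:
            return
        es = load_epochs(f)
        try:
            sel = _subject_selection(cfg, es, s_sel)
        except ValueError as exc:
            log.warning("excluding %s: %s", f.name, exc)
            continue
        n_ok += 1
        yield es, sel
    if n_ok < 2:
        raise RuntimeError(f"fewer than 2 usable subjects for {modality}")


def _stage_erp(cfg: RunConfig, out: Path) -> list[Path]:
    outputs = []
    peaks: dict = {}
    for modality in cfg.cohort.modalities:
        subject_avgs = []
        for es, sel in _usable_epoch_sets(cfg, out, modality):
            subject_avgs.append({c: es.epochs[idx].mean(axis=0)
                                 for c, idx in sel.items()})
            chans, fs = es.channel_names, es.sampling_rate
        ga = grand_average(subject_avgs, chans, fs, cfg.epoch_window_s,
                           trials_per_subject=cfg.cohort.n_select)
        gapath = out / f"{modality}_grand_average.h5"
        save_grand_average(ga, gapath)
        outputs.append(gapath)
        peaks[modality] = {}
        for cond in ga.means:
            if cond == "control":
                continue
            peaks[modality][cond] = {
                comp: {"amplitude": pm.amplitude, "latency_ms": pm.latency_ms}
                for comp in DEFAULT_SEARCH_WINDOWS_MS
                for pm in [peak_from_grand_average(ga, cond, comp)]}
        snap = scalp_snapshot(ga, [c for c in ga.means if c != "control"][0])
        snap_path = out / f"{modality}_scalp_snapshot.tsv"
        lines = ["time_ms\tchannel\tamplitude"]
        for t, chmap in snap.items():
            for ch, v in chmap.items():
                lines.append(f"{t:g}\t{ch}\t{v:.4f}")
        snap_path.write_text("\n".join(lines) + "\n")
        outputs.append(snap_path)
    pk = out / "erp_peaks.json"
    pk.write_text(json.dumps(peaks, indent=2))
    outputs.append(pk)
    return outputs


def _stage_features(cfg: RunConfig, out: Path) -> list[Path]:
    fcfg = cfg.features.to_config()
    outputs = []
    for modality in cfg.cohort.modalities:
        pooled: dict[tuple[str, str], list[FeatureMatrix]] = {}
        for es, sel in _usable_epoch_sets(cfg, out, modality):
            for cond, idx in sel.items():
                mats = extract_all(subset_epochs(es, idx), fcfg)
                for m in METHODS:
                    pooled.setdefault((m, cond), []).append(mats[m])
        for (m, cond), parts in pooled.items():
            fm = FeatureMatrix(
                matrix=np.vstack([p.matrix for p in parts]),
                names=list(parts[0].names),
                labels=[lb for p in parts for lb in p.labels],
                meta=dict(parts[0].meta))
            path = out / f"{modality}_{cond}_{m}.h5"
            save_features(fm, path)
            outputs.append(path)
    return outputs


def _stage_classify(cfg: RunConfig, out: Path) -> list[Path]:
    cv = cfg.cv.to_config(cfg.seed)
    results = {}
    for modality in cfg.cohort.modalities:
        for m in METHODS:
            ctrl_path = _require(out / f"{modality}_control_{m}.h5", "features")
            ctrl = load_features(ctrl_path)
            for cond in ("explosion", "burning"):
                stim_path = out / f"{modality}_{cond}_{m}.h5"
                if not stim_path.exists():
                    continue
                stim = load_features(stim_path)
                X, y, prov = assemble_dataset(stim, ctrl, balance=True,
                                              seed=cv.seed)
                folds = crossval_train_eval(X, y, cv, names=stim.names)
                results[f"{m}/{cond}/{modality}"] = {
                    "provenance": prov,
                    "folds": [{"tp": f.tp, "fn": f.fn, "tn": f.tn, "fp": f.fp}
                              for f in folds]}
    path = out / "fold_metrics.json"
    path.write_text(json.dumps(results, indent=2))
    return [path]


def _stage_report(cfg: RunConfig, out: Path) -> list[Path]:
    src = _require(out / "fold_metrics.json", "classify")
    raw = json.loads(src.read_text())
    runs = {}
    for key, entry in raw.items():
        m, cond, modality = key.split("/")
        runs[(m, cond, modality)] = [FoldMetrics(**f) for f in entry["folds"]]
    build_report(runs, out_json=out / "detection_report.json",
                 out_tsv=out / "detection_report.tsv")
    return [out / "detection_report.json", out / "detection_report.tsv"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "erp": _stage_erp,
    "features": _stage_features,
    "classify": _stage_classify,
    "report": _stage_report,
}


def run_stage(name: str, cfg: RunConfig, out_dir: str | Path | None = None) -> list[Path]:
    """Run one pipeline stage, writing artifacts and a manifest."""
    if name not in _STAGE_FNS:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    log.info("running stage %s (config %s, seed %d)", name, cfg.config_hash(),
             cfg.seed)
    outputs = _STAGE_FNS[name](cfg, out)
    _write_manifest(name, cfg, out, inputs=[], outputs=outputs)
    return outputs


def run_all(cfg: RunConfig, out_dir: str | Path | None = None) -> dict[str, list[Path]]:
    """The full chain in order."""
    return {stage: run_stage(stage, cfg, out_dir) for stage in STAGES}
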