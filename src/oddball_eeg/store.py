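"""HDF5 persistence for epochs, grand averages and feature matrices."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .features import FeatureMatrix
from .preprocess import EpochSet, GrandAverage

__all__ = ["save_epochs", "load_epochs", "save_grand_average",
           "load_grand_average", "save_features", "load_features"]


def _str_list(ds) -> list[str]:
    return [s.decode() if isinstance(s, bytes) else str(s) for s in ds[()]]


def save_epochs(es: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=es.epochs, compression="gzip")
        f["channel_names"] = np.array(es.channel_names, dtype="S")
        f["labels"] = np.array(es.labels, dtype="S")
        f["kept"] = es.kept
        f["reject_reasons"] = np.array(es.reject_reasons, dtype="S")
        f.attrs["sampling_rate"] = es.sampling_rate
        f.attrs["window_s"] = es.window_s
        f.attrs["subject_id"] = es.subject_id
        f.attrs["baseline_corrected"] = es.baseline_corrected


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            epochs=f["epochs"][()],
            channel_names=_str_list(f["channel_names"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            window_s=tuple(f.attrs["window_s"]),
            labels=_str_list(f["labels"]),
            subject_id=str(f.attrs["subject_id"]),
            kept=f["kept"][()].astype(bool),
            reject_reasons=_str_list(f["reject_reasons"]),
            baseline_corrected=bool(f.attrs["baseline_corrected"]),
        )


def save_grand_average(ga: GrandAverage, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for cond in ga.means:
            f[f"mean/{cond}"] = ga.means[cond]
            f[f"sd/{cond}"] = ga.sds[cond]
        f["channel_names"] = np.array(ga.channel_names, dtype="S")
        f.attrs["sampling_rate"] = ga.sampling_rate
        f.attrs["window_s"] = ga.window_s
        f.attrs["n_subjects"] = ga.n_subjects
        f.attrs["trials_per_subject"] = ga.trials_per_subject


def load_grand_average(path: str | Path) -> GrandAverage:
    with h5py.File(path, "r") as f:
        conds = list(f["mean"].keys())
        return GrandAverage(
            means={c: f[f"mean/{c}"][()] for c in conds},
            sds={c: f[f"sd/{c}"][()] for c in conds},
            channel_names=_str_list(f["channel_names"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            window_s=tuple(f.attrs["window_s"]),
            n_subjects=int(f.attrs["n_subjects"]),
            trials_per_subject=int(f.attrs["trials_per_subject"]),
        )


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=fm.matrix, compression="gzip")
        f["names"] = np.array(fm.names, dtype="S")
        f["labels"] = np.array(fm.labels, dtype="S")
        f.attrs["normalized"] = fm.normalized
        f.attrs["meta"] = repr(fm.meta)


def load_features(path: str | Path) -> FeatureMatrix:
    import ast
    with h5py.File(path, "r") as f:
        return FeatureMatrix(
            matrix=f["matrix"][()],
            names=_str_list(f["names"]),
            labels=_str_list(f["labels"]),
            normalized=bool(f.attrs["normalized"]),
            meta=ast.literal_eval(str(f.attrs["meta"])),
        )
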