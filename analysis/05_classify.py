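#!/usr/bin/env python
"""Stimulus-vs-control detection with a linear SVM.

For each feature method (VAR, PSD, DWT, DVP), condition (explosion,
burning) and modality, balance the pooled dataset (304 + 304 in the full
profile), run 10 repeated stratified 80/20 splits with fold-internal
[-1, 1] normalization, and store per-fold confusion counts.
"""

import argparse
import json
from pathlib import Path

from oddball_eeg.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="scratch/pipeline")
    args = ap.parse_args()

    cfg = RunConfig.model_validate({"seed": args.seed, "out_dir": args.out})
    (path,) = run_stage("classify", cfg)
    raw = json.loads(Path(path).read_text())
    for key, entry in sorted(raw.items()):
        folds = entry["folds"]
        acc = sum((f["tp"] + f["tn"]) / sum(f.values()) for f in folds) / len(folds)
        print(f"{key:35s} mean accuracy {100 * acc:5.1f}%")


if __name__ == "__main__":
    main()
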