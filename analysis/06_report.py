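#!/usr/bin/env python
"""Assemble the detection report.

Emits the methods x conditions x modalities grid of mean fold metrics,
audio-visual minus visual-only deltas in percentage points, fold-wise
Welch tests, and the best method per column, as JSON and TSV in
results/.
"""

import argparse
import json
from pathlib import Path

from oddball_eeg.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="scratch/pipeline")
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    cfg = RunConfig.model_validate({"seed": args.seed, "out_dir": args.out})
    run_stage("report", cfg)
    out = Path(args.out)
    results = Path(args.results)
    results.mkdir(exist_ok=True)
    for name in ("detection_report.json", "detection_report.tsv"):
        (results / name).write_text((out / name).read_text())

    rep = json.loads((results / "detection_report.json").read_text())
    print("accuracy deltas, audio-visual minus visual-only (pp):")
    for method, conds in rep["deltas"].items():
        for cond, metrics in conds.items():
            welch = rep["welch"][method][cond]
            print(f"  {method:4s} {cond:9s} {metrics['accuracy']:+6.2f} pp "
                  f"(p={welch['p']:.4f})")
    print("best method per column:", rep["best_method"])


if __name__ == "__main__":
    main()
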