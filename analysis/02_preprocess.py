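#!/usr/bin/env python
"""Preprocess every simulated session.

Chain per subject: drop the unreliable channels (O1, PO7), 50/100 Hz
notch + 0.5-40 Hz zero-phase band-pass, epoch -0.5..+1.0 s around each
marker, baseline-correct on the pre-onset mean, and flag outlier trials
(variance/kurtosis, robust z > 3 within each condition ensemble).
Writes per-subject epoch HDF5 files and a rejection log.
"""

import argparse

from oddball_eeg.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="scratch/pipeline")
    args = ap.parse_args()

    cfg = RunConfig.model_validate({"seed": args.seed, "out_dir": args.out})
    outputs = run_stage("preprocess", cfg)
    rej = [p for p in outputs if p.name == "rejection_log.tsv"][0]
    n_rejected = sum(1 for line in rej.read_text().splitlines()
                     if "\trejected\t" in line)
    print(f"wrote {len(outputs) - 1} epoch files; {n_rejected} trials "
          f"flagged (see {rej})")


if __name__ == "__main__":
    main()
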