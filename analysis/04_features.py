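#!/usr/bin/env python
"""Extract single-trial features on the 0-660 ms window.

VAR (44), Welch PSD in 1-30 Hz (275 under the printed-dims grid), db8
level-3 DWT approximations (341), and the fused DVP vector (660), for
the 38 selected trials per condition per subject, pooled across the
cohort.  Matrices are persisted as HDF5 with per-column provenance.
"""

import argparse

from oddball_eeg.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="scratch/pipeline")
    ap.add_argument("--profile", default="printed-dims",
                    choices=["printed-dims", "natural"])
    args = ap.parse_args()

    cfg = RunConfig.model_validate({"seed": args.seed, "out_dir": args.out,
                                    "features": {"profile": args.profile}})
    outputs = run_stage("features", cfg)
    from oddball_eeg.store import load_features
    for p in outputs:
        if p.name.endswith("_DVP.h5"):
            fm = load_features(p)
            print(f"{p.name}: {fm.n_trials} trials x {fm.n_features} features")


if __name__ == "__main__":
    main()
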