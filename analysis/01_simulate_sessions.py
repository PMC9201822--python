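#!/usr/bin/env python
"""Simulate the two experimental cohorts (visual-only and audio-visual).

Eight subjects per modality, each a full session of 8 blocks x 30 trials
(40 explosion / 40 burning / 160 control), written as EDF recordings with
tab-delimited event tables.  Large raw files go under scratch/.
"""

import argparse

from oddball_eeg.pipeline import RunConfig, run_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="scratch/pipeline")
    ap.add_argument("--quick", action="store_true",
                    help="2 subjects, 2 blocks (smoke scale)")
    args = ap.parse_args()

    overrides = {"seed": args.seed, "out_dir": args.out}
    if args.quick:
        overrides["session"] = {"n_blocks": 2}
        overrides["cohort"] = {"n_subjects": 2, "n_select": 10}
    cfg = RunConfig.model_validate(overrides)
    outputs = run_stage("simulate", cfg)
    print(f"wrote {len(outputs)} files under {args.out}")
    print("per session: 240 trials, 40 explosion / 40 burning / 160 control"
          if not args.quick else "quick mode: 60 trials per session")


if __name__ == "__main__":
    main()
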