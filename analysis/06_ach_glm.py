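"""Acetylcholine GLM: which task factors explain the bulk ACh signal.

Builds the boxcar + lick-kernel design matrix from each archived session's
trial table, fits the L1-penalized Normal GLM to the synthetic ACh trace and
ranks task factors by dAIC (AIC of the partial model without the factor
minus AIC of the full model).  The pre-stimulus transient dominates by
construction, with pre-reward licking second — reward delivery itself and
post-reward licking carry nothing.

Run 01_simulate_course.py first.
"""

import argparse
from pathlib import Path

import pandas as pd

from prhpop import ach_glm, pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--sessions-dir", type=Path,
                    default=Path("results") / "sessions")
    ap.add_argument("--out", type=Path,
                    default=Path("results") / "ach_factors.csv")
    args = ap.parse_args()

    frames = []
    for h5 in sorted(args.sessions_dir.glob("T*.h5")):
        bundle = pipeline.load_session(h5)
        if bundle.ach is None:
            continue
        stage = bundle.trials["stage"].iloc[0]
        design = ach_glm.build_design(bundle.trials, bundle.frame_rate_hz)
        fa = ach_glm.factor_delta_aic(bundle.ach, design, seed=args.seed)
        fa.insert(0, "stage", stage)
        frames.append(fa)
        top = fa.iloc[0]
        print(f"{stage}: top factor {top['factor']} "
              f"(dAIC {top['delta_aic']:.0f})")

    df = pd.concat(frames, ignore_index=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
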