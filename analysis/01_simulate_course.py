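"""Simulate a full synthetic training course and archive the sessions.

Generates one session per stage T1..T5 with the default planted effects —
direction gain decaying with learning, speed gain growing, a retrogradely
expanding pre-reward signal, and sign-flipping expected-outcome cells — and
writes each session (HDF5 tensors + trial-table CSV) under results/sessions/.
"""

import argparse
from pathlib import Path

from prhpop import pipeline, trial_world
from prhpop.trial_world import PlantedEffects, StageConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-trials", type=int, default=200)
    ap.add_argument("--n-neurons", type=int, default=60)
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results") / "sessions")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    fx = PlantedEffects(n_neurons=args.n_neurons)
    for i, stage in enumerate(("T1", "T2", "T3", "T4", "T5")):
        cfg = StageConfig.for_stage(stage)
        bundle = trial_world.simulate_session(cfg, args.n_trials, fx,
                                              seed=args.seed + i)
        paths = pipeline.save_session(bundle, args.out_dir / f"{stage}.h5")
        counts = bundle.trials["outcome"].value_counts().to_dict()
        print(f"{stage}: {len(bundle.trials)} trials, "
              f"{bundle.fluorescence.shape[0]} neurons, outcomes {counts} "
              f"-> {paths[0].name}")


if __name__ == "__main__":
    main()
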