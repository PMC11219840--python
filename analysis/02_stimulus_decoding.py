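"""Decode stimulus direction and speed from each archived session.

Expectation under the planted learning dynamics: direction decodability falls
toward its shuffle band by T5 while speed decodability rises above it —
the signature of a sensory prediction error that suppresses learned,
outcome-predictive features and amplifies surprising ones.

Run 01_simulate_course.py first.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from prhpop import decoding, events, pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--sessions-dir", type=Path,
                    default=Path("results") / "sessions")
    ap.add_argument("--out", type=Path,
                    default=Path("results") / "stimulus_decoding.csv")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    rows = []
    for h5 in sorted(args.sessions_dir.glob("T*.h5")):
        bundle = pipeline.load_session(h5)
        ev = events.estimate_events(bundle.fluorescence,
                                    bundle.frame_rate_hz).s_hat
        row = {"stage": bundle.trials["stage"].iloc[0]}
        # direction on correct trials: error trials retain the naive gain
        correct = bundle.trials["outcome"].isin(["hit", "CR"]).to_numpy()
        trials_c = bundle.trials.loc[correct]
        y = decoding.labels_from_trials(trials_c, "direction")
        feat = decoding.window_features(ev, trials_c, "sample", y=y,
                                        frame_rate_hz=bundle.frame_rate_hz)
        model = decoding.fit_decoder(feat, rng=rng)
        null = decoding.label_shuffle_null(feat, n=200, rng=rng)
        row.update(direction_acc=model.accuracy, direction_pct95=null.pct95)

        y = decoding.labels_from_trials(bundle.trials, "speed")
        feat = decoding.window_features(ev, bundle.trials, "sample", y=y,
                                        frame_rate_hz=bundle.frame_rate_hz)
        model = decoding.fit_decoder_resampled(feat, n_resamples=20, rng=rng)
        null = decoding.label_shuffle_null(feat, n=200, resample=True, rng=rng)
        row.update(speed_acc=model.accuracy, speed_pct95=null.pct95)
        rows.append(row)
        print(f"{row['stage']}: direction {row['direction_acc']:.2f} "
              f"(95th null {row['direction_pct95']:.2f}), "
              f"speed {row['speed_acc']:.2f} (95th null {row['speed_pct95']:.2f})")

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"\nwrote {args.out}")
    if len(df) >= 2:
        print("direction T1->T5 change: "
              f"{df['direction_acc'].iloc[-1] - df['direction_acc'].iloc[0]:+.2f}; "
              "speed T1->T5 change: "
              f"{df['speed_acc'].iloc[-1] - df['speed_acc'].iloc[0]:+.2f}")


if __name__ == "__main__":
    main()
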