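"""Expected-outcome analysis: pre-stimulus decoders and the sign flip.

Trains hit vs non-hit decoders on pre-stimulus activity, tests them across
the trial, and projects population activity on the decision-variable axis.
The planted expected-outcome cells carry a weak pre-stimulus preference that
reverses at report, so the cross-temporal accuracy at report should fall
below the 5th-percentile band and the hit/CR projection trajectories should
cross between pre-stimulus and report.

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
                    default=Path("results") / "expected_outcome.csv")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    rows = []
    proj_frames = []
    for h5 in sorted(args.sessions_dir.glob("T*.h5")):
        bundle = pipeline.load_session(h5)
        stage = bundle.trials["stage"].iloc[0]
        ev = events.estimate_events(bundle.fluorescence,
                                    bundle.frame_rate_hz).s_hat
        y = decoding.labels_from_trials(bundle.trials, "hit_vs_nonhit")
        ct = decoding.cross_temporal(ev, bundle.trials, y, "pre_stim",
                                     bundle.frame_rate_hz, n_null=500, rng=rng)
        tl = ct.timeline
        wi_rep = int(np.argmin(np.abs(ct.test_starts_s - tl.report_start_s)))
        rows.append({
            "stage": stage,
            "prestim_acc": float(ct.accuracy[0]),
            "report_acc": float(ct.accuracy[wi_rep]),
            "report_below_chance": bool(ct.sig_below[wi_rep]),
            "report_pct5": float(ct.pct5[wi_rep]),
        })
        feat = decoding.window_features(ev, bundle.trials, "pre_stim", y=y,
                                        frame_rate_hz=bundle.frame_rate_hz)
        model = decoding.fit_decoder(feat, rng=rng)
        traj = decoding.project_decision_variable(ev, bundle.trials, model,
                                                  bundle.frame_rate_hz)
        pf = pd.DataFrame({k: traj[k] for k in ("time_s", "hit", "miss",
                                                "FA", "CR")})
        pf.insert(0, "stage", stage)
        proj_frames.append(pf)
        r = rows[-1]
        print(f"{stage}: pre-stim acc {r['prestim_acc']:.2f}, report acc "
              f"{r['report_acc']:.2f} (5th null {r['report_pct5']:.2f}, "
              f"below chance: {r['report_below_chance']})")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    proj_path = args.out.with_name("decision_variable_projection.csv")
    pd.concat(proj_frames, ignore_index=True).to_csv(proj_path, index=False)
    print(f"\nwrote {args.out} and {proj_path}")


if __name__ == "__main__":
    main()
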