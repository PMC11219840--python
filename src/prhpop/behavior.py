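"""Go/no-go behavioral measures and adaptive training rules.

d' (sensitivity) is the difference of inverse-normal-transformed hit and
false-alarm rates.  Stage advancement requires d' above a stage-specific
threshold for a number of consecutive sessions (0.45 for the naive stage,
1.68 thereafter).  During training, punishment (time-outs, air puffs) and
stimulus probabilities adapt to performance and response biases measured on
sliding windows of recent trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import logging

import numpy as np
from scipy.stats import norm

log = logging.getLogger(__name__)

#: stage -> (d' threshold, consecutive sessions required)
STAGE_CRITERIA = {
    "T1": (0.45, 2),
    "T2": (1.68, 2),
    "T3": (1.68, 2),
    "T4": (1.68, 2),
    "T5": (1.68, 2),
}

TIMEOUT_BOUNDS_S = (2.0, 10.0)
AIRPUFF_BOUNDS = (0, 5)
AIRPUFF_TIMEOUT_THRESHOLD_S = 7.0
PUNISH_WINDOW = 50
BIAS_WINDOW = 20


def dprime(hit_rate: float, fa_rate: float, n_trials: int = None) -> float:
    """d' = Phi^-1(HR) - Phi^-1(FAR), with rates clamped to [1/2N, 1-1/2N].

    The clamp (applied when ``n_trials`` is given, with N the per-category
    trial count) keeps degenerate 0/1 rates finite.
    """
    lo, hi = 0.0, 1.0
    if n_trials:
        lo, hi = 1.0 / (2 * n_trials), 1.0 - 1.0 / (2 * n_trials)
    hr = float(np.clip(hit_rate, lo, hi))
    far = float(np.clip(fa_rate, lo, hi))
    return float(norm.ppf(hr) - norm.ppf(far))


def dprime_from_outcomes(outcomes) -> float:
    """d' from a sequence of hit/miss/FA/CR outcome strings."""
    o = np.asarray(outcomes)
    n_nm = int(np.isin(o, ["hit", "miss"]).sum())
    n_m = int(np.isin(o, ["FA", "CR"]).sum())
    if n_nm == 0 or n_m == 0:
        raise ValueError("need both nonmatch and match trials")
    hr = (o == "hit").sum() / n_nm
    far = (o == "FA").sum() / n_m
    n = min(n_nm, n_m)
    return dprime(hr, far, n_trials=n)


def stage_advance(dprime_history, stage: str) -> bool:
    """True when the last sessions meet the stage's consecutive-d' criterion."""
    thresh, n_consec = STAGE_CRITERIA[stage]
    hist = list(dprime_history)
    if len(hist) < n_consec:
        return False
    return all(d > thresh for d in hist[-n_consec:])


@dataclass(frozen=True)
class BiasState:
    """Adaptive punishment and stimulus-probability settings."""

    timeout_s: float = 2.0
    airpuffs: int = 0
    p_nonmatch: float = 0.5
    p_AP_within_nonmatch: float = 0.5
    p_AA_within_match: float = 0.5


def bias_update(outcomes, lick_ports, state: BiasState,
                literal_ratio_rule: bool = True) -> BiasState:
    """One pass of the adaptive training rules on recent trials.

    ``outcomes`` is the recent outcome history (most recent last);
    ``lick_ports`` gives the port the animal favored per trial (here: 'go'
    for lick, 'nogo' for withhold), used for report-bias detection.

    Rules (50-trial window for punishment, 20-trial for biases):

    * <70% correct  -> +1 s time-out (max 10 s); if the time-out already
      exceeds 7 s, +1 air puff (max 5).
    * >50% misses   -> -2 s time-out and -2 air puffs (floored at minima).
    * Report bias X - Y (favored minus neglected port fraction) > 0.25 ->
      nonmatch/match split 0.35/0.65 toward the neglected side; > 0.5 -> 0.2/0.8.
    * Primacy/recency bias among the two nonmatch (or match) conditions:
      moderate -> 0.4/0.6 split, severe -> 0.3/0.7.  The protocol's tabulated criterion is
      (X/Y - 0.5) > 0.55 (moderate) / > 0.6 (severe); with
      ``literal_ratio_rule=False`` the difference X - Y is used with the same
      cut-offs instead.
    """
    o = np.asarray(outcomes)
    new = state
    if len(o) >= PUNISH_WINDOW:
        win = o[-PUNISH_WINDOW:]
        correct = np.isin(win, ["hit", "CR"]).mean()
        miss = (win == "miss").mean()
        if miss > 0.5:
            new = replace(new, timeout_s=new.timeout_s - 2.0,
                          airpuffs=new.airpuffs - 2)
        elif correct < 0.7:
            timeout = new.timeout_s + 1.0
            puffs = new.airpuffs
            if new.timeout_s > AIRPUFF_TIMEOUT_THRESHOLD_S:
                puffs += 1
            new = replace(new, timeout_s=timeout, airpuffs=puffs)
        new = replace(new,
                      timeout_s=float(np.clip(new.timeout_s, *TIMEOUT_BOUNDS_S)),
                      airpuffs=int(np.clip(new.airpuffs, *AIRPUFF_BOUNDS)))
    else:
        log.warning("punishment window shorter than %d trials; no-op", PUNISH_WINDOW)

    ports = np.asarray(lick_ports)
    if len(ports) >= BIAS_WINDOW:
        win = ports[-BIAS_WINDOW:]
        p_go = (win == "go").mean()
        favored, x = ("go", p_go) if p_go >= 0.5 else ("nogo", 1 - p_go)
        y = 1.0 - x
        # licking = the nonmatch (go) port; neglected port's stimulus gains probability
        if x - y > 0.5:
            p_fav = 0.2
        elif x - y > 0.25:
            p_fav = 0.35
        else:
            p_fav = None
        if p_fav is not None:
            p_nm = p_fav if favored == "go" else 1.0 - p_fav
            new = replace(new, p_nonmatch=p_nm)

    return new


def condition_bias_split(correct_frac_favored: float, correct_frac_other: float,
                         literal_ratio_rule: bool = True):
    """Stimulus-probability split for a primacy/recency bias.

    Returns (p_favored, p_neglected) or None when no rule fires.  X is the
    fraction correct on the favored condition, Y on the neglected one.
    """
    x, y = correct_frac_favored, correct_frac_other
    if literal_ratio_rule:
        stat = (x / y - 0.5) if y > 0 else float("inf")
    else:
        stat = x - y
    if stat > 0.6:
        return (0.3, 0.7)
    if stat > 0.55:
        return (0.4, 0.6)
    return None
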