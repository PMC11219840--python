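"""Choice selectivity of speed-tuned neurons.

A neuron's stimulus response (SR) is the peak of its trial-averaged event
rate within the sample or test period.  Choice selectivity contrasts error
(miss, FA) against correct (hit, CR) trials:

    CS = (SR_error - SR_correct) / (SR_error + SR_correct)

CS lies in [-1, 1]; positive values mean stronger responses on error trials.
Records with a zero denominator are undefined and dropped.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .decoding import Timeline

log = logging.getLogger(__name__)

CORRECT_OUTCOMES = ("hit", "CR")
ERROR_OUTCOMES = ("miss", "FA")


def stimulus_response(ev: np.ndarray, trials: pd.DataFrame,
                      trial_mask: np.ndarray, period: str,
                      frame_rate_hz: float) -> np.ndarray:
    """Per-neuron SR: peak of the trial-averaged event rate in a period."""
    trial_mask = np.asarray(trial_mask, bool)
    if not trial_mask.any():
        raise ValueError("empty trial subset")
    if period not in ("sample", "test"):
        raise ValueError("period must be 'sample' or 'test'")
    timeline = Timeline.from_trials(trials, frame_rate_hz)
    start_s, width_s = timeline.period_window(period)
    sub = trials.loc[trial_mask]
    n_frames = min(len(timeline.frames_for(tr, start_s, width_s))
                   for _, tr in sub.iterrows())
    acc = np.zeros((ev.shape[0], n_frames))
    for _, tr in sub.iterrows():
        frames = timeline.frames_for(tr, start_s, width_s)[:n_frames]
        acc += ev[:, frames]
    mean_trace = acc / trial_mask.sum()
    return mean_trace.max(axis=1)


def choice_selectivity(sr_error: np.ndarray, sr_correct: np.ndarray) -> np.ndarray:
    """(SR_error - SR_correct) / (SR_error + SR_correct); NaN when both are 0."""
    sr_error = np.asarray(sr_error, float)
    sr_correct = np.asarray(sr_correct, float)
    if np.any(sr_error < 0) or np.any(sr_correct < 0):
        raise ValueError("stimulus responses must be >= 0")
    denom = sr_error + sr_correct
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = (sr_error - sr_correct) / denom
    cs[denom == 0] = np.nan
    return cs


def selectivity_table(ev: np.ndarray, trials: pd.DataFrame,
                      neuron_mask: Optional[np.ndarray], period: str,
                      frame_rate_hz: float) -> pd.DataFrame:
    """CS records for the masked (e.g. speed-significant) neurons.

    Neurons with an undefined ratio (no activity in either condition) are
    dropped and logged.
    """
    outcome = trials["outcome"].to_numpy()
    correct = np.isin(outcome, CORRECT_OUTCOMES)
    error = np.isin(outcome, ERROR_OUTCOMES)
    sr_c = stimulus_response(ev, trials, correct, period, frame_rate_hz)
    sr_e = stimulus_response(ev, trials, error, period, frame_rate_hz)
    cs = choice_selectivity(sr_e, sr_c)
    df = pd.DataFrame({
        "neuron_id": np.arange(ev.shape[0]),
        "SR_correct": sr_c, "SR_error": sr_e, "CS": cs, "period": period,
    })
    if neuron_mask is not None:
        df = df[np.asarray(neuron_mask, bool)]
    n_drop = int(df["CS"].isna().sum())
    if n_drop:
        log.warning("dropped %d neurons with undefined CS (zero responses)", n_drop)
    return df.dropna(subset=["CS"]).reset_index(drop=True)
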