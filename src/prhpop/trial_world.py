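"""Synthetic delayed non-match-to-sample (DNMS) session generator.

Produces stage-structured go/no-go whisker DNMS sessions — trial tables,
neurons x frames fluorescence tensors with planted population codes, bulk
acetylcholine traces and lick trains — so that every downstream analysis
(deconvolution, decoding, selectivity, GLM) can be exercised and validated
against known ground truth.

Task structure: a sample stimulus (anterior or posterior rotor direction, fast
or slow speed) is followed after a delay by a test stimulus.  Non-matching
direction pairs are rewarded under go/no-go: lick on non-match = hit, withhold
= miss; lick on match = false alarm (FA), withhold = correct rejection (CR).
Training advances through stages T1..T5 that change condition probabilities
and delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

STAGES = ("T1", "T2", "T3", "T4", "T5")

#: default within-trial period durations in seconds (delay comes from the
#: stage schedule; a short post period separates trials)
DEFAULT_PERIODS_S = {"pre_stim": 1.0, "sample": 1.0, "test": 1.0, "report": 1.5}
POST_TRIAL_S = 1.0
DEFAULT_FRAME_RATE_HZ = 32.6

#: reward is delivered this long after report onset on hit trials
REWARD_LATENCY_S = 0.3


@dataclass
class StageConfig:
    """Stimulus-schedule parameters for one training stage."""

    stage_id: str = "T3"
    p_nonmatch: float = 0.5
    include_PA: bool = False
    p_slow: float = 0.05
    delay_options_ms: list = field(default_factory=lambda: [(100.0, 1.0)])
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    period_durations_s: dict = field(default_factory=lambda: dict(DEFAULT_PERIODS_S))
    behavioral_dprime: float = 1.68
    #: optional (start, end, n_sessions) ramp of p_nonmatch, used in T1
    p_nonmatch_ramp: Optional[tuple] = None
    #: probability that a nonmatch trial is AP (vs PA); bias-adjustable
    p_AP_within_nonmatch: float = 0.5
    p_AA_within_match: float = 0.5

    def __post_init__(self):
        for name in ("p_nonmatch", "p_slow", "p_AP_within_nonmatch", "p_AA_within_match"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        probs = [p for _, p in self.delay_options_ms]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("delay option probabilities must be >= 0 and sum to 1")
        if self.stage_id not in STAGES:
            raise ValueError(f"unknown stage {self.stage_id!r}")

    @classmethod
    def for_stage(cls, stage: str, **overrides) -> "StageConfig":
        """Default configuration of a named training stage.

        T1 ramps the nonmatch probability 0.9 -> 0.5 over five sessions and
        uses a 100 ms delay; PA is introduced at T3; T4 extends the delay to
        2 s; T5 draws delays of 2/3/4 s with probabilities 0.5/0.25/0.25 and
        raises the slow-speed fraction from 5% to 25%.
        """
        base = dict(
            T1=dict(p_nonmatch=0.9, p_nonmatch_ramp=(0.9, 0.5, 5), include_PA=False,
                    p_slow=0.05, delay_options_ms=[(100.0, 1.0)], behavioral_dprime=0.6),
            T2=dict(p_nonmatch=0.5, include_PA=False, p_slow=0.05,
                    delay_options_ms=[(100.0, 1.0)], behavioral_dprime=1.7),
            T3=dict(p_nonmatch=0.5, include_PA=True, p_slow=0.05,
                    delay_options_ms=[(100.0, 1.0)], behavioral_dprime=1.8),
            T4=dict(p_nonmatch=0.5, include_PA=True, p_slow=0.05,
                    delay_options_ms=[(2000.0, 1.0)], behavioral_dprime=1.9),
            T5=dict(p_nonmatch=0.5, include_PA=True, p_slow=0.25,
                    delay_options_ms=[(2000.0, 0.5), (3000.0, 0.25), (4000.0, 0.25)],
                    behavioral_dprime=1.9),
        )[stage]
        base.update(overrides)
        return cls(stage_id=stage, **base)


@dataclass
class PlantedEffects:
    """Ground-truth population codes injected into the synthetic spikes.

    Neurons are partitioned into direction, speed, reward and expected-outcome
    cells (remaining neurons are untuned).  The per-stage gain schedules
    emulate the learning dynamics the analyses are meant to detect: direction
    gain decays with training on correct trials (but is retained on error
    trials), speed gain grows, the reward signal's lead before reward delivery
    expands retrogradely, and expected-outcome cells carry a weak pre-stimulus
    preference that reverses sign in the report window.
    """

    n_neurons: int = 60
    frac_direction: float = 0.25
    frac_speed: float = 0.25
    frac_reward: float = 0.2
    frac_expected: float = 0.2
    direction_gain_by_stage: dict = field(default_factory=lambda: dict(
        T1=3.0, T2=2.2, T3=1.5, T4=0.7, T5=0.0))
    speed_gain_by_stage: dict = field(default_factory=lambda: dict(
        T1=0.5, T2=1.2, T3=1.8, T4=2.4, T5=3.0))
    speed_error_bias: float = 1.0
    reward_gain: float = 4.0
    reward_onset_lead_s_by_stage: dict = field(default_factory=lambda: dict(
        T1=0.0, T2=0.5, T3=1.0, T4=1.5, T5=2.0))
    #: sd (log scale) of the per-neuron response-gain multiplier
    gain_spread: float = 0.5
    #: 1.0 = one shared reward code for AP and PA hits; 0.0 = disjoint codes
    #: (each reward cell prefers one nonmatch condition and responds to the
    #: other at this fraction of its gain)
    reward_condition_alignment: float = 1.0
    expected_gain: float = 1.2
    expected_report_gain: float = 4.0
    expected_sign_flip: bool = True
    spike_baseline_hz: float = 0.3
    kernel_decay_s: float = 0.5
    photon_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_direction, self.frac_speed, self.frac_reward, self.frac_expected)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
            raise ValueError("neuron fractions must be >= 0 and sum to <= 1")
        for sched in (self.direction_gain_by_stage, self.speed_gain_by_stage,
                      self.reward_onset_lead_s_by_stage):
            if any(v < 0 for v in sched.values()):
                raise ValueError("gains and leads must be >= 0")

    def cell_roles(self) -> tuple:
        """Per-neuron (roles, preferences, gain multipliers) lists.

        Everything depends only on (seed, neuron index), so growing the
        population never reassigns existing neurons.  ``preference`` breaks
        the within-class symmetry: 'A'/'P' for direction cells, 'slow'/'fast'
        for speed cells, 'AP+hit'-style condition+outcome tags for reward
        cells, 'hit'/'non' for expected-outcome cells.  Gain multipliers are
        lognormal (sd ``gain_spread`` on the log scale), giving each planted
        cell an individual response strength.
        """
        cuts = np.cumsum([self.frac_direction, self.frac_speed,
                          self.frac_reward, self.frac_expected])
        names = ["direction", "speed", "reward", "expected"]
        roles, prefs, gain_mult = [], [], []
        for i in range(self.n_neurons):
            rng_i = _neuron_rng(self.seed, i, salt=0)
            u = rng_i.random()
            role = "untuned"
            for name, cut in zip(names, cuts):
                if u < cut:
                    role = name
                    break
            if role == "direction":
                pref = "A" if rng_i.random() < 0.5 else "P"
            elif role == "speed":
                pref = "slow" if rng_i.random() < 0.5 else "fast"
            elif role == "expected":
                pref = "hit" if rng_i.random() < 0.5 else "non"
            elif role == "reward":
                # mixed outcome selectivity: hit-responders carry the leading
                # reward signal; a minority of omission responders fire at the
                # expected reward time on unrewarded trials (the mixed signs
                # give weight-shuffle nulls their power)
                cond = "AP" if rng_i.random() < 0.5 else "PA"
                out = "hit" if rng_i.random() < 0.7 else "nonhit"
                pref = f"{cond}+{out}"
            else:
                pref = ""
            roles.append(role)
            prefs.append(pref)
            # heterogeneous response strength: lognormal gain multiplier
            gain_mult.append(float(np.exp(rng_i.normal(0.0, self.gain_spread))))
        return roles, prefs, gain_mult

    def cell_groups(self) -> dict:
        """Index arrays of each planted cell class (realized assignment)."""
        roles = self.cell_roles()[0]
        roles = np.asarray(roles)
        return {name: np.nonzero(roles == name)[0]
                for name in ("direction", "speed", "reward", "expected", "untuned")}


def _neuron_rng(seed: int, i: int, salt: int = 1) -> np.random.Generator:
    """Stream keyed by (seed, neuron, salt); independent of population size."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(int(i), int(salt))))


@dataclass
class SessionBundle:
    """One synthetic session: trial table plus frame-aligned tensors."""

    trials: pd.DataFrame
    fluorescence: np.ndarray          # neurons x frames
    ground_truth_spikes: np.ndarray   # neurons x frames, counts
    frame_rate_hz: float
    ach: Optional[np.ndarray] = None  # frames,
    effects: Optional[PlantedEffects] = None

    def __post_init__(self):
        n_frames = int(self.trials["post_end"].max()) if len(self.trials) else 0
        for arr in (self.fluorescence, self.ground_truth_spikes):
            if arr.shape[-1] != n_frames:
                raise ValueError("array frame axis does not match the trial table")
        if self.ach is not None and self.ach.shape[-1] != n_frames:
            raise ValueError("ach frame axis does not match the trial table")

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]


TRIAL_COLUMNS = [
    "trial_id", "session_index", "stage", "sample_dir", "test_dir", "speed",
    "category", "delay_ms", "outcome",
    "pre_stim_start", "pre_stim_end", "sample_start", "sample_end",
    "delay_start", "delay_end", "test_start", "test_end",
    "report_start", "report_end", "post_start", "post_end",
    "reward_frame", "lick_frames",
]


def _sec_to_frames(seconds: float, fr: float) -> int:
    return max(1, int(round(seconds * fr)))


def generate_trial_schedule(cfg: StageConfig, n_trials: int,
                            seed: int, session_index: int = 0) -> pd.DataFrame:
    """Draw a stage-structured trial schedule with frame-indexed periods.

    Periods are contiguous half-open frame windows
    ``[pre_stim | sample | delay | test | report | post)`` laid out back to
    back across the session.  Outcomes, licks and reward frames are filled by
    :func:`simulate_choices` / :func:`simulate_licks`.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rng = np.random.default_rng(seed)
    fr = cfg.frame_rate_hz
    per = cfg.period_durations_s

    p_nm = cfg.p_nonmatch
    if cfg.p_nonmatch_ramp is not None:
        start, end, n_sess = cfg.p_nonmatch_ramp
        frac = min(session_index, n_sess - 1) / max(n_sess - 1, 1)
        p_nm = start + (end - start) * frac

    delays, dprobs = zip(*cfg.delay_options_ms)
    rows = []
    frame = 0
    for t in range(n_trials):
        nonmatch = rng.random() < p_nm
        if nonmatch:
            if cfg.include_PA:
                sample = "A" if rng.random() < cfg.p_AP_within_nonmatch else "P"
            else:
                sample = "A"
            test = "P" if sample == "A" else "A"
        else:
            sample = test = "A" if rng.random() < cfg.p_AA_within_match else "P"
        speed = "slow" if rng.random() < cfg.p_slow else "fast"
        delay_ms = float(delays[rng.choice(len(delays), p=dprobs)])

        n_pre = _sec_to_frames(per["pre_stim"], fr)
        n_sample = _sec_to_frames(per["sample"], fr)
        n_delay = _sec_to_frames(delay_ms / 1000.0, fr)
        n_test = _sec_to_frames(per["test"], fr)
        n_report = _sec_to_frames(per["report"], fr)
        n_post = _sec_to_frames(POST_TRIAL_S, fr)
        edges = frame + np.cumsum([0, n_pre, n_sample, n_delay, n_test, n_report, n_post])
        rows.append(dict(
            trial_id=t, session_index=session_index, stage=cfg.stage_id,
            sample_dir=sample, test_dir=test, speed=speed,
            category="nonmatch" if nonmatch else "match", delay_ms=delay_ms,
            outcome=None,
            pre_stim_start=edges[0], pre_stim_end=edges[1],
            sample_start=edges[1], sample_end=edges[2],
            delay_start=edges[2], delay_end=edges[3],
            test_start=edges[3], test_end=edges[4],
            report_start=edges[4], report_end=edges[5],
            post_start=edges[5], post_end=edges[6],
            reward_frame=None, lick_frames=None,
        ))
        frame = int(edges[6])
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    if n_trials == 0:
        df = pd.DataFrame(columns=TRIAL_COLUMNS)
    return df


def simulate_choices(table: pd.DataFrame, dprime: float, seed: int) -> pd.DataFrame:
    """Fill go/no-go outcomes from a target sensitivity d'.

    Uses the symmetric-criterion mapping HR = Phi(d'/2), FAR = Phi(-d'/2), so
    fraction correct = Phi(d'/2) under a balanced nonmatch/match split.  This
    reproduces the task's performance anchors (80% correct at d' ~ 1.68, 70%
    at d' ~ 1.05).
    """
    if dprime < 0:
        raise ValueError("dprime must be >= 0")
    rng = np.random.default_rng(seed)
    hr = norm.cdf(dprime / 2.0)
    far = norm.cdf(-dprime / 2.0)
    out = table.copy()
    u = rng.random(len(out))
    nonmatch = out["category"].to_numpy() == "nonmatch"
    outcome = np.where(nonmatch,
                       np.where(u < hr, "hit", "miss"),
                       np.where(u < far, "FA", "CR"))
    out["outcome"] = outcome
    return out


def simulate_licks(table: pd.DataFrame, stage: str, seed: int,
                   baseline_rate_hz: Optional[float] = None,
                   report_rate_hz: float = 6.0) -> pd.DataFrame:
    """Fill lick trains and reward frames.

    Licking outside the report window is Poisson at a stage-dependent baseline
    rate that falls with training (licking becomes restricted to the reporting
    period).  Hit and FA trials carry a report-window lick burst; hit trials
    are rewarded ``REWARD_LATENCY_S`` after report onset and always lick at
    the reward frame, with consumption licks afterwards.
    """
    rng = np.random.default_rng(seed)
    if baseline_rate_hz is None:
        baseline_rate_hz = {"T1": 1.5, "T2": 1.0, "T3": 0.7, "T4": 0.4, "T5": 0.2}[stage]
    fr = DEFAULT_FRAME_RATE_HZ
    out = table.copy()
    lick_lists, reward_frames = [], []
    for _, tr in out.iterrows():
        licks = []
        # baseline licking anywhere outside the report window
        p_base = baseline_rate_hz / fr
        for a, b in ((tr.pre_stim_start, tr.report_start), (tr.report_end, tr.post_end)):
            hits = np.nonzero(rng.random(int(b - a)) < p_base)[0] + int(a)
            licks.extend(int(f) for f in hits)
        reward = None
        if tr.outcome in ("hit", "FA"):
            burst_start = int(tr.report_start + round(0.1 * fr))
            p = report_rate_hz / fr
            span = np.arange(burst_start, tr.report_end)
            licks.extend(int(f) for f in span[rng.random(len(span)) < p])
            if tr.outcome == "hit":
                reward = int(tr.report_start + round(REWARD_LATENCY_S * fr))
                licks.append(reward)  # the rewarded lick itself
                # consumption licks after reward
                span = np.arange(reward + 1, tr.report_end)
                licks.extend(int(f) for f in span[rng.random(len(span)) < p])
        lick_lists.append(sorted(set(licks)))
        reward_frames.append(reward)
    out["lick_frames"] = lick_lists
    out["reward_frame"] = reward_frames
    return out


def _stage_val(sched: dict, stage: str) -> float:
    return float(sched[stage])


def simulate_population(table: pd.DataFrame, fx: PlantedEffects,
                        noise_seed: Optional[int] = None) -> SessionBundle:
    """Render spikes and fluorescence with the planted condition codes.

    Spike counts are Poisson per frame around a baseline rate, with additive
    rate bumps for each planted cell class (see :class:`PlantedEffects`).
    Fluorescence is an AR(1) convolution of the spikes (decay
    ``kernel_decay_s``) plus white Gaussian noise.  Neuron identity (roles,
    preferences) is governed by ``fx.seed``; the stochastic draw of spikes
    and photon noise by ``noise_seed`` (defaults to ``fx.seed``), so the same
    planted population can be re-imaged across sessions with fresh noise.
    Each neuron draws from its own child stream, so adding neurons never
    perturbs existing ones.
    """
    if table["outcome"].isna().any():
        raise ValueError("outcomes must be filled before simulating activity")
    if len(table) == 0:
        raise ValueError("cannot simulate a session with no trials")
    fr = DEFAULT_FRAME_RATE_HZ
    n_frames = int(table["post_end"].max())
    stage = str(table["stage"].iloc[0])
    n = fx.n_neurons

    rate = np.full((n, n_frames), fx.spike_baseline_hz / fr)
    roles, prefs, gain_mult = fx.cell_roles()
    roles = np.asarray(roles)
    prefs = np.asarray(prefs)
    gain_mult = np.asarray(gain_mult)

    def add(neurons, frames_mask, gain_hz):
        if len(neurons) and frames_mask.any():
            idx = np.nonzero(frames_mask)[0]
            rate[np.ix_(neurons, idx)] += \
                (gain_hz * gain_mult[neurons])[:, None] / fr
    pref_A = np.nonzero((roles == "direction") & (prefs == "A"))[0]
    pref_P = np.nonzero((roles == "direction") & (prefs == "P"))[0]
    g_dir_stage = _stage_val(fx.direction_gain_by_stage, stage)
    g_dir_T1 = _stage_val(fx.direction_gain_by_stage, "T1")
    g_speed = _stage_val(fx.speed_gain_by_stage, stage)
    lead = _stage_val(fx.reward_onset_lead_s_by_stage, stage)

    exp_pref_hit = np.nonzero((roles == "expected") & (prefs == "hit"))[0]
    exp_pref_non = np.nonzero((roles == "expected") & (prefs == "non"))[0]

    for _, tr in table.iterrows():
        correct = tr.outcome in ("hit", "CR")
        g_dir = g_dir_stage if correct else g_dir_T1  # retained on error trials
        for period in ("sample", "test"):
            a, b = int(tr[f"{period}_start"]), int(tr[f"{period}_end"])
            win = np.zeros(n_frames, bool)
            win[a:b] = True
            d = tr.sample_dir if period == "sample" else tr.test_dir
            add(pref_A if d == "A" else pref_P, win, g_dir)
            g = g_speed
            if not correct and stage != "T1":
                g += fx.speed_error_bias
            speed_cells = np.nonzero((roles == "speed") &
                                     (prefs == tr.speed))[0]
            add(speed_cells, win, g)
        if tr.outcome == "hit" and tr.reward_frame is not None:
            start = max(int(tr.pre_stim_start), int(tr.reward_frame) - int(round(lead * fr)))
            win = np.zeros(n_frames, bool)
            win[start: int(tr.report_end)] = True
            cond = "AP" if tr.sample_dir == "A" else "PA"
            rew_pref = np.nonzero((roles == "reward") &
                                  (prefs == f"{cond}+hit"))[0]
            other = "PA" if cond == "AP" else "AP"
            rew_other = np.nonzero((roles == "reward") &
                                   (prefs == f"{other}+hit"))[0]
            add(rew_pref, win, fx.reward_gain)
            add(rew_other, win, fx.reward_gain * fx.reward_condition_alignment)
        elif tr.outcome in ("miss", "FA", "CR"):
            # omission responders: fire from the time reward would have come
            omit = int(tr.report_start) + int(round(REWARD_LATENCY_S * fr))
            rep = np.zeros(n_frames, bool)
            rep[omit: int(tr.report_end)] = True
            rew_nonhit = np.nonzero((roles == "reward") &
                                    np.char.endswith(prefs.astype(str),
                                                     "+nonhit"))[0]
            add(rew_nonhit, rep, fx.reward_gain)
        # expected-outcome cells: weak pre-stimulus offset by future outcome,
        # strong report response whose preferred class reverses when flipped
        hit_trial = tr.outcome == "hit"
        pre = np.zeros(n_frames, bool)
        pre[int(tr.pre_stim_start): int(tr.pre_stim_end)] = True
        add(exp_pref_hit if hit_trial else exp_pref_non, pre, fx.expected_gain)
        rep = np.zeros(n_frames, bool)
        rep[int(tr.report_start): int(tr.report_end)] = True
        if fx.expected_sign_flip:
            add(exp_pref_non if hit_trial else exp_pref_hit, rep, fx.expected_report_gain)
        else:
            add(exp_pref_hit if hit_trial else exp_pref_non, rep, fx.expected_report_gain)

    if noise_seed is None:
        noise_seed = fx.seed
    gamma = np.exp(-1.0 / (fr * fx.kernel_decay_s))
    spikes = np.empty((n, n_frames))
    F = np.empty((n, n_frames))
    from scipy.signal import lfilter
    for i in range(n):
        rng_i = _neuron_rng(noise_seed, i, salt=1)
        spikes[i] = rng_i.poisson(rate[i])
        calcium = lfilter([1.0], [1.0, -gamma], spikes[i])
        F[i] = calcium + rng_i.normal(0.0, fx.photon_noise_sd, n_frames)
    return SessionBundle(trials=table, fluorescence=F, ground_truth_spikes=spikes,
                         frame_rate_hz=fr, effects=fx)


def simulate_ach(table: pd.DataFrame, seed: int,
                 pre_stim_amp: float = 1.5, lick_amp: float = 0.6,
                 noise_sd: float = 0.3) -> np.ndarray:
    """Bulk acetylcholine trace: pre-stimulus transient + pre-reward licking.

    The trace carries a boxcar transient through the pre-stimulus period of
    every trial and a component locked to licks that precede reward (all licks
    on miss/FA/CR trials; pre-reward licks on hit trials).  There is
    deliberately no component locked to reward consumption.  The trace is
    z-scored per trial, matching how bulk sensor fluorescence is normalized.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(table["post_end"].max()) if len(table) else 0
    trace = np.zeros(n_frames)
    for _, tr in table.iterrows():
        trace[int(tr.pre_stim_start): int(tr.pre_stim_end)] += pre_stim_amp
        licks = tr.lick_frames or []
        reward = tr.reward_frame
        for f in licks:
            if reward is not None and f >= reward:
                continue  # no consumption-locked release
            trace[int(f)] += lick_amp
    # smooth the lick impulses into a transient
    from scipy.ndimage import gaussian_filter1d
    trace = gaussian_filter1d(trace, sigma=2.0)
    trace = trace + rng.normal(0.0, noise_sd, n_frames)
    out = trace.copy()
    for _, tr in table.iterrows():
        a, b = int(tr.pre_stim_start), int(tr.post_end)
        seg = trace[a:b]
        sd = seg.std()
        out[a:b] = (seg - seg.mean()) / (sd if sd > 0 else 1.0)
    return out


def simulate_session(cfg: StageConfig, n_trials: int, fx: PlantedEffects,
                     seed: int, session_index: int = 0,
                     with_ach: bool = True) -> SessionBundle:
    """Full pipeline: schedule -> choices -> licks -> population (+ ACh)."""
    ss = np.random.SeedSequence(seed)
    s_sched, s_choice, s_lick, s_ach = [int(s.generate_state(1)[0] % (2**31))
                                        for s in ss.spawn(4)]
    table = generate_trial_schedule(cfg, n_trials, s_sched, session_index)
    table = simulate_choices(table, cfg.behavioral_dprime, s_choice)
    table = simulate_licks(table, cfg.stage_id, s_lick)
    bundle = simulate_population(table, fx,
                                 noise_seed=int(ss.generate_state(1)[0] % (2**31)))
    if with_ach:
        bundle.ach = simulate_ach(table, s_ach)
    return bundle
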