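"""Orchestration: session I/O and the end-to-end multi-stage course.

``run_course`` simulates a training course (stages T1..T5, several sessions
each), runs the analysis chain on every session — event estimation, direction
/ speed / reward / expected-outcome decoding, decodable onset, choice
selectivity, acetylcholine GLM — and writes stage-resolved summary tables
plus a manifest of every emitted file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from . import ach_glm, behavior, decoding, events, selectivity, trial_world
from .trial_world import PlantedEffects, SessionBundle, StageConfig

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# session I/O


def save_session(bundle: SessionBundle, h5_path, csv_path=None) -> list:
    """Write a session to HDF5 (/F, /spikes, /ach) + trial-table CSV."""
    h5_path = Path(h5_path)
    csv_path = Path(csv_path) if csv_path else h5_path.with_suffix(".trials.csv")
    with h5py.File(h5_path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["frame_rate_hz"] = bundle.frame_rate_hz
        f.create_dataset("F", data=bundle.fluorescence)
        f.create_dataset("spikes", data=bundle.ground_truth_spikes)
        if bundle.ach is not None:
            f.create_dataset("ach", data=bundle.ach)
        if bundle.effects is not None:
            f.attrs["effects_json"] = json.dumps(asdict(bundle.effects))
    df = bundle.trials.copy()
    df["lick_frames"] = df["lick_frames"].map(
        lambda v: ";".join(str(int(x)) for x in v) if isinstance(v, (list, tuple)) else "")
    df.to_csv(csv_path, index=False)
    return [h5_path, csv_path]


def load_session(h5_path, csv_path=None) -> SessionBundle:
    """Read a session back; inverse of :func:`save_session`."""
    h5_path = Path(h5_path)
    csv_path = Path(csv_path) if csv_path else h5_path.with_suffix(".trials.csv")
    with h5py.File(h5_path, "r") as f:
        if "F" not in f:
            raise KeyError("missing /F dataset: not a session file")
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            raise ValueError("unsupported session schema version")
        F = f["F"][()]
        spikes = f["spikes"][()]
        ach = f["ach"][()] if "ach" in f else None
        fr = float(f.attrs["frame_rate_hz"])
        effects = None
        if "effects_json" in f.attrs:
            effects = PlantedEffects(**json.loads(f.attrs["effects_json"]))
    df = pd.read_csv(csv_path)
    df["lick_frames"] = df["lick_frames"].map(
        lambda v: [int(x) for x in str(v).split(";")] if isinstance(v, str) and v else [])
    df["reward_frame"] = df["reward_frame"].map(
        lambda v: None if pd.isna(v) else int(v))
    return SessionBundle(trials=df, fluorescence=F, ground_truth_spikes=spikes,
                         frame_rate_hz=fr, ach=ach, effects=effects)


def io_roundtrip(bundle: SessionBundle, path) -> SessionBundle:
    """Write then re-read a bundle (arrays exact, table equal)."""
    save_session(bundle, path)
    return load_session(path)


# ---------------------------------------------------------------------------
# the replica course


@dataclass
class RunConfig:
    """One configuration drives the whole course."""

    stages: tuple = ("T1", "T2", "T3", "T4", "T5")
    sessions_per_stage: int = 4
    n_trials: int = 200
    effects: PlantedEffects = field(default_factory=PlantedEffects)
    seed: int = 0
    out_dir: Optional[str] = None
    n_null: int = 200          # label-shuffle repetitions per session decoder
    n_ct_null: int = 200       # weight-shuffle repetitions per test window
    n_resamples: int = 20      # minority-resampling repetitions (speed decoder)
    save_sessions: bool = False
    with_ach_glm: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "out_dir"}},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def analyze_session(bundle: SessionBundle, rng: np.random.Generator,
                    cfg: RunConfig) -> dict:
    """The per-session analysis chain; returns one summary row."""
    trials = bundle.trials
    fr = bundle.frame_rate_hz
    em = events.estimate_events(bundle.fluorescence, fr)
    ev = em.s_hat
    row = {
        "stage": trials["stage"].iloc[0],
        "session_index": int(trials["session_index"].iloc[0]),
        "n_trials": len(trials),
        "dprime": behavior.dprime_from_outcomes(trials["outcome"]),
    }

    # direction decoding on correct trials (error trials retain the naive
    # direction gain by construction, so they are analyzed separately)
    correct = trials["outcome"].isin(["hit", "CR"]).to_numpy()
    trials_c = trials.loc[correct]
    y_dir = decoding.labels_from_trials(trials_c, "direction")
    feat = decoding.window_features(ev, trials_c, "sample", y=y_dir, frame_rate_hz=fr)
    dir_model = decoding.fit_decoder(feat, rng=rng)
    null = decoding.label_shuffle_null(feat, n=cfg.n_null, rng=rng)
    row.update(direction_acc=dir_model.accuracy, direction_pct95=null.pct95)

    y_spd = decoding.labels_from_trials(trials, "speed")
    feat_spd = decoding.window_features(ev, trials, "sample", y=y_spd, frame_rate_hz=fr)
    spd_model = decoding.fit_decoder_resampled(feat_spd, n_resamples=cfg.n_resamples,
                                               rng=rng)
    null_spd = decoding.label_shuffle_null(feat_spd, n=cfg.n_null, resample=True,
                                           rng=rng)
    row.update(speed_acc=spd_model.accuracy, speed_pct95=null_spd.pct95)

    # reward decoder trained on report, cross-temporal onset
    y_rew = decoding.labels_from_trials(trials, "hit_vs_nonhit")
    ct = decoding.cross_temporal(ev, trials, y_rew, "report", fr,
                                 n_null=cfg.n_ct_null, rng=rng)
    onset = decoding.decodable_onset(ct)
    tl = ct.timeline
    row.update(
        reward_report_acc=float(ct.accuracy[
            np.argmin(np.abs(ct.test_starts_s - tl.report_start_s))]),
        reward_onset_s=onset,
        reward_onset_before_reward_s=(
            None if onset is None else
            (tl.report_start_s + trial_world.REWARD_LATENCY_S) - onset),
    )

    # expected outcome: pre-stimulus decoder tested at report
    ct_exp = decoding.cross_temporal(ev, trials, y_rew, "pre_stim", fr,
                                     n_null=cfg.n_ct_null, rng=rng)
    wi_rep = int(np.argmin(np.abs(ct_exp.test_starts_s - tl.report_start_s)))
    wi_pre = 0
    row.update(
        expected_pre_acc=float(ct_exp.accuracy[wi_pre]),
        expected_report_acc=float(ct_exp.accuracy[wi_rep]),
        expected_report_below_chance=bool(ct_exp.sig_below[wi_rep]),
    )

    # choice selectivity of speed-significant neurons
    sig = decoding.significant_weights(feat_spd, n=min(cfg.n_null, 200), rng=rng)
    if sig.any() and np.isin(trials["outcome"], selectivity.ERROR_OUTCOMES).any():
        cs = selectivity.selectivity_table(ev, trials, sig, "test", fr)
        row["mean_cs"] = float(cs["CS"].mean()) if len(cs) else np.nan
    else:
        row["mean_cs"] = np.nan

    if cfg.with_ach_glm and bundle.ach is not None:
        design = ach_glm.build_design(trials, fr)
        fa = ach_glm.factor_delta_aic(bundle.ach, design, seed=int(rng.integers(2**31)))
        row["top_ach_factor"] = fa.iloc[0]["factor"]
        row["ach_pre_stim_delta_aic"] = float(
            fa.set_index("factor").loc["pre_stimulus", "delta_aic"])
    return row


def run_course(cfg: RunConfig) -> dict:
    """Simulate and analyze the full course; returns summary + manifest."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    files = []
    for stage in cfg.stages:
        t0 = time.perf_counter()
        stage_cfg = StageConfig.for_stage(stage)
        for s_idx in range(cfg.sessions_per_stage):
            child = ss.spawn(1)[0]
            seed = int(child.generate_state(1)[0] % (2**31))
            bundle = trial_world.simulate_session(
                stage_cfg, cfg.n_trials, cfg.effects, seed, session_index=s_idx)
            if out_dir and cfg.save_sessions:
                files += save_session(bundle, out_dir / f"{stage}_s{s_idx}.h5")
            rows.append(analyze_session(bundle, rng, cfg))
        log.info("stage %s analyzed in %.1f s", stage, time.perf_counter() - t0,
                 extra={"stage": stage})
    summary = pd.DataFrame(rows)
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"), "files": {}}
    if out_dir:
        spath = out_dir / "course_summary.csv"
        summary.to_csv(spath, index=False)
        files.append(spath)
        for p in files:
            manifest["files"][str(Path(p).name)] = {
                "operation": "run_course", "config_hash": cfg.config_hash(),
                "seed": cfg.seed}
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
    return {"summary": summary, "manifest": manifest}
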