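"""Schedule statistics, outcome calibration and planted-signal plumbing."""

import numpy as np
import pytest

from prhpop import behavior, trial_world
from prhpop.trial_world import PlantedEffects, StageConfig


class TestSchedule:
    def test_empty_schedule_has_valid_schema(self):
        df = trial_world.generate_trial_schedule(
            StageConfig.for_stage("T2"), 0, seed=0)
        assert len(df) == 0
        assert list(df.columns) == trial_world.TRIAL_COLUMNS

    def test_condition_frequencies_match_config(self):
        # 3-binomial-SD agreement at n=10000
        n = 10000
        cfg = StageConfig.for_stage("T4")
        df = trial_world.generate_trial_schedule(cfg, n, seed=1)
        for value, p in [
            ((df["speed"] == "slow").mean(), cfg.p_slow),
            ((df["category"] == "nonmatch").mean(), cfg.p_nonmatch),
        ]:
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(value - p) < 3 * sd

    def test_t5_delay_distribution(self):
        # delay draws of 2/3/4 s at probabilities 0.5/0.25/0.25
        n = 10000
        df = trial_world.generate_trial_schedule(
            StageConfig.for_stage("T5"), n, seed=2)
        counts = df["delay_ms"].value_counts(normalize=True)
        for ms, p in [(2000.0, 0.5), (3000.0, 0.25), (4000.0, 0.25)]:
            assert abs(counts[ms] - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_pa_trials_only_with_include_pa(self):
        df2 = trial_world.generate_trial_schedule(
            StageConfig.for_stage("T2"), 500, seed=3)
        nm2 = df2[df2["category"] == "nonmatch"]
        assert (nm2["sample_dir"] == "A").all()
        df3 = trial_world.generate_trial_schedule(
            StageConfig.for_stage("T3"), 500, seed=3)
        nm3 = df3[df3["category"] == "nonmatch"]
        assert (nm3["sample_dir"] == "P").any()

    def test_t1_nonmatch_ramp(self):
        cfg = StageConfig.for_stage("T1")
        first = trial_world.generate_trial_schedule(cfg, 4000, 4, session_index=0)
        last = trial_world.generate_trial_schedule(cfg, 4000, 4, session_index=4)
        assert (first["category"] == "nonmatch").mean() > 0.85
        assert abs((last["category"] == "nonmatch").mean() - 0.5) < 0.03

    def test_period_windows_contiguous_and_ordered(self):
        df = trial_world.generate_trial_schedule(
            StageConfig.for_stage("T5"), 20, seed=5)
        for _, tr in df.iterrows():
            assert tr.pre_stim_start < tr.pre_stim_end == tr.sample_start
            assert tr.sample_end == tr.delay_start
            assert tr.delay_end == tr.test_start
            assert tr.test_end == tr.report_start
            assert tr.report_end == tr.post_start < tr.post_end
        starts = df["pre_stim_start"].to_numpy()
        assert (np.diff(starts) > 0).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            StageConfig(stage_id="T2", p_nonmatch=1.5)
        with pytest.raises(ValueError):
            StageConfig(stage_id="T2", delay_options_ms=[(100.0, 0.4)])

    def test_schedule_reproducible(self):
        cfg = StageConfig.for_stage("T3")
        a = trial_world.generate_trial_schedule(cfg, 50, seed=7)
        b = trial_world.generate_trial_schedule(cfg, 50, seed=7)
        assert a.equals(b)


class TestChoices:
    @pytest.mark.parametrize("dprime, frac", [(0.0, 0.5), (1.68, 0.80), (6.0, 1.0)])
    def test_fraction_correct_tracks_dprime(self, dprime, frac):
        cfg = StageConfig.for_stage("T2")
        df = trial_world.generate_trial_schedule(cfg, 10000, seed=8)
        df = trial_world.simulate_choices(df, dprime, seed=9)
        correct = df["outcome"].isin(["hit", "CR"]).mean()
        assert correct == pytest.approx(frac, abs=0.02)

    def test_empirical_dprime_recovers_input(self):
        cfg = StageConfig.for_stage("T2")
        df = trial_world.generate_trial_schedule(cfg, 10000, seed=10)
        df = trial_world.simulate_choices(df, 1.68, seed=11)
        assert behavior.dprime_from_outcomes(df["outcome"]) == pytest.approx(1.68, abs=0.1)

    def test_outcome_category_consistency(self):
        cfg = StageConfig.for_stage("T3")
        df = trial_world.simulate_choices(
            trial_world.generate_trial_schedule(cfg, 300, seed=12), 1.0, seed=13)
        nm = df["category"] == "nonmatch"
        assert df.loc[nm, "outcome"].isin(["hit", "miss"]).all()
        assert df.loc[~nm, "outcome"].isin(["FA", "CR"]).all()


@pytest.fixture(scope="module")
def licked():
    out = {}
    for stage in ("T1", "T5"):
        cfg = StageConfig.for_stage(stage)
        df = trial_world.generate_trial_schedule(cfg, 150, seed=14)
        df = trial_world.simulate_choices(df, cfg.behavioral_dprime, seed=15)
        out[stage] = trial_world.simulate_licks(df, stage, seed=16)
    return out


class TestLicks:

    def test_prestim_licking_declines_with_training(self, licked):
        def prestim_rate(df):
            total = 0
            for _, tr in df.iterrows():
                total += sum(tr.pre_stim_start <= f < tr.pre_stim_end
                             for f in tr.lick_frames)
            return total / len(df)
        assert prestim_rate(licked["T1"]) > prestim_rate(licked["T5"])

    def test_hit_trials_lick_at_reward(self, licked):
        hits = licked["T5"][licked["T5"]["outcome"] == "hit"]
        assert len(hits) > 0
        for _, tr in hits.iterrows():
            assert tr.reward_frame in tr.lick_frames
            assert tr.report_start <= tr.reward_frame < tr.report_end

    def test_reward_frame_only_on_hits(self, licked):
        df = licked["T5"]
        has_reward = df["reward_frame"].notna()
        assert (has_reward == (df["outcome"] == "hit")).all()

    def test_cr_trials_sparse_in_report(self, licked):
        df = licked["T5"]
        crs = df[df["outcome"] == "CR"]
        hits = df[df["outcome"] == "hit"]
        def report_licks(rows):
            return np.mean([sum(r.report_start <= f < r.report_end
                                for f in r.lick_frames) for _, r in rows.iterrows()])
        assert report_licks(crs) < report_licks(hits)


class TestPopulation:
    def test_effects_validation(self):
        with pytest.raises(ValueError):
            PlantedEffects(frac_direction=0.6, frac_speed=0.6)
        with pytest.raises(ValueError):
            PlantedEffects(direction_gain_by_stage={s: -1 for s in trial_world.STAGES})

    def test_bundle_shapes_and_reproducibility(self, small_bundle):
        n_frames = int(small_bundle.trials["post_end"].max())
        assert small_bundle.fluorescence.shape == (24, n_frames)
        assert small_bundle.ground_truth_spikes.min() >= 0
        again = trial_world.simulate_session(
            StageConfig.for_stage("T2"), 60, PlantedEffects(n_neurons=24), seed=123)
        np.testing.assert_array_equal(again.fluorescence, small_bundle.fluorescence)

    def test_adding_neurons_preserves_existing_ones(self, small_bundle):
        bigger = trial_world.simulate_session(
            StageConfig.for_stage("T2"), 60, PlantedEffects(n_neurons=30), seed=123)
        np.testing.assert_array_equal(bigger.fluorescence[:24],
                                      small_bundle.fluorescence)

    def test_reward_cells_respond_before_reward_on_hits(self, small_bundle):
        fx = small_bundle.effects
        roles, prefs, _ = fx.cell_roles()
        hit_cells = np.nonzero([r == "reward" and p.endswith("+hit")
                                for r, p in zip(roles, prefs)])[0]
        spikes = small_bundle.ground_truth_spikes
        lead = fx.reward_onset_lead_s_by_stage["T2"]
        fr = small_bundle.frame_rate_hz
        hit_pre, nonhit_pre = [], []
        for _, tr in small_bundle.trials.iterrows():
            if tr.outcome == "hit":
                a = int(tr.reward_frame - round(lead * fr))
                hit_pre.append(spikes[np.ix_(hit_cells,
                                             range(a, int(tr.reward_frame)))].mean())
            else:
                a, b = int(tr.report_start), int(tr.report_end)
                nonhit_pre.append(spikes[np.ix_(hit_cells, range(a, b))].mean())
        assert np.mean(hit_pre) > 2 * np.mean(nonhit_pre)


class TestAch:
    def test_per_trial_zscore(self):
        cfg = StageConfig.for_stage("T2")
        df = trial_world.generate_trial_schedule(cfg, 30, seed=20)
        df = trial_world.simulate_choices(df, 1.7, seed=21)
        df = trial_world.simulate_licks(df, "T2", seed=22)
        ach = trial_world.simulate_ach(df, seed=23)
        for _, tr in df.iterrows():
            seg = ach[int(tr.pre_stim_start): int(tr.post_end)]
            assert abs(seg.mean()) < 1e-9
            assert seg.std() == pytest.approx(1.0, abs=1e-6)

    def test_prestim_elevation(self):
        cfg = StageConfig.for_stage("T2")
        df = trial_world.generate_trial_schedule(cfg, 60, seed=24)
        df = trial_world.simulate_choices(df, 1.7, seed=25)
        df = trial_world.simulate_licks(df, "T2", seed=26)
        ach = trial_world.simulate_ach(df, seed=27)
        pre, post = [], []
        for _, tr in df.iterrows():
            pre.append(ach[int(tr.pre_stim_start): int(tr.pre_stim_end)].mean())
            post.append(ach[int(tr.post_start): int(tr.post_end)].mean())
        assert np.mean(pre) > np.mean(post) + 0.5
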