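"""Decoder correctness, null calibration, cross-temporal machinery."""

import numpy as np
import pandas as pd
import pytest

from prhpop import decoding, events, trial_world
from prhpop.decoding import LabeledFeatures
from prhpop.trial_world import PlantedEffects, StageConfig


def make_features(n=100, p=12, signal=0.0, imbalance=0.5, seed=0):
    """Gaussian features with an optional planted mean shift on class 1."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < imbalance).astype(int)
    X = rng.normal(size=(n, p))
    X[y == 1, : p // 2] += signal
    return LabeledFeatures(X=decoding.zscore_columns(X), y=y)


class TestWindowFeatures:
    def test_zero_variance_neuron_maps_to_zero(self, small_bundle, small_events):
        ev = small_events.copy()
        ev[0] = 3.0  # constant neuron
        y = decoding.labels_from_trials(small_bundle.trials, "direction")
        feat = decoding.window_features(ev, small_bundle.trials, "sample", y=y,
                                        frame_rate_hz=small_bundle.frame_rate_hz)
        assert (feat.X[:, 0] == 0).all()

    def test_features_are_zscored(self, small_bundle, small_events):
        y = decoding.labels_from_trials(small_bundle.trials, "direction")
        feat = decoding.window_features(small_events, small_bundle.trials,
                                        "report", y=y,
                                        frame_rate_hz=small_bundle.frame_rate_hz)
        np.testing.assert_allclose(feat.X.mean(axis=0), 0.0, atol=1e-9)
        sds = feat.X.std(axis=0)
        np.testing.assert_allclose(sds[sds > 0], 1.0, atol=1e-9)

    def test_hand_computed_two_trial_zscore(self):
        # two trials, one neuron: means 1 and 3 -> z-scores -1, +1
        trials = trial_world.generate_trial_schedule(
            StageConfig.for_stage("T2"), 2, seed=0)
        ev = np.zeros((1, int(trials["post_end"].max())))
        for val, (_, tr) in zip([1.0, 3.0], trials.iterrows()):
            ev[0, int(tr.sample_start): int(tr.sample_end)] = val
        feat = decoding.window_features(ev, trials, "sample", y=np.array([0, 1]),
                                        frame_rate_hz=32.6)
        np.testing.assert_allclose(feat.X[:, 0], [-1.0, 1.0])

    def test_empty_window_rejected(self, small_bundle, small_events):
        with pytest.raises(ValueError):
            decoding.window_features(small_events, small_bundle.trials,
                                     ("sample", 0.0), y=None,
                                     frame_rate_hz=small_bundle.frame_rate_hz)


class TestFitDecoder:
    def test_separable_data_high_accuracy(self):
        feat = make_features(n=100, signal=3.0, seed=1)
        model = decoding.fit_decoder(feat)
        assert model.accuracy >= 0.95

    def test_chance_on_label_independent_data(self, rng):
        feat = make_features(n=200, signal=0.0, seed=2)
        model = decoding.fit_decoder(feat, rng=rng)
        null = decoding.label_shuffle_null(feat, n=200, rng=rng)
        assert null.pct5 <= model.accuracy <= null.pct95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            decoding.fit_decoder(LabeledFeatures(X=np.ones((10, 2)),
                                                 y=np.zeros(10)))

    def test_hard_margin_matches_brute_force_separator(self):
        # <= 8 trials x 2 neurons: compare with exhaustive direction search
        rng = np.random.default_rng(3)
        X = np.array([[1.0, 1.2], [0.8, 1.5], [1.1, 0.9], [1.3, 1.1],
                      [-1.0, -0.8], [-1.2, -1.1], [-0.7, -1.3], [-1.1, -0.9]])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        feat = LabeledFeatures(X=X, y=y)
        model = decoding.fit_decoder(feat, folds=2, C=1e6)
        # brute force: maximize margin over a fine angle grid
        best_margin, best_w = -np.inf, None
        for theta in np.linspace(0, np.pi, 20000, endpoint=False):
            w = np.array([np.cos(theta), np.sin(theta)])
            proj = X @ w
            lo = proj[y == 1].min() if proj[y == 1].min() > proj[y == 0].max() \
                else None
            if lo is None:
                proj = -proj
                if proj[y == 1].min() <= proj[y == 0].max():
                    continue
                w = -w
            margin = (X @ w)[y == 1].min() - (X @ w)[y == 0].max()
            if margin > best_margin:
                best_margin, best_w = margin, w
        cos = model.weights @ best_w / np.linalg.norm(model.weights)
        assert cos == pytest.approx(1.0, abs=1e-2)


class TestResampledDecoder:
    def test_balanced_input_matches_plain_decoder(self, rng):
        feat = make_features(n=80, signal=2.0, imbalance=0.5, seed=4)
        plain = decoding.fit_decoder(feat, rng=np.random.default_rng(0))
        res = decoding.fit_decoder_resampled(feat, n_resamples=20, rng=rng)
        assert res.accuracy == pytest.approx(plain.accuracy, abs=0.06)

    def test_informative_minority_detected(self, rng):
        feat = make_features(n=200, signal=2.5, imbalance=0.06, seed=5)
        res = decoding.fit_decoder_resampled(feat, n_resamples=20, rng=rng)
        null = decoding.label_shuffle_null(feat, n=100, resample=True, rng=rng)
        assert res.accuracy > null.pct95

    def test_no_imbalance_bias_without_signal(self, rng):
        feat = make_features(n=200, signal=0.0, imbalance=0.06, seed=6)
        res = decoding.fit_decoder_resampled(feat, n_resamples=20, rng=rng)
        null = decoding.label_shuffle_null(feat, n=100, resample=True, rng=rng)
        assert null.pct5 <= res.accuracy <= null.pct95


class TestLabelShuffleNull:
    def test_null_centered_at_chance_for_balanced_labels(self, rng):
        feat = make_features(n=100, signal=1.0, imbalance=0.5, seed=7)
        null = decoding.label_shuffle_null(feat, n=100, rng=rng)
        se = null.samples.std() / np.sqrt(len(null.samples))
        assert abs(null.samples.mean() - 0.5) < max(3 * se, 0.02)
        assert null.pct5 <= np.median(null.samples) <= null.pct95

    def test_deterministic_under_fixed_seed(self):
        feat = make_features(n=60, signal=0.5, seed=8)
        a = decoding.label_shuffle_null(feat, n=30, rng=np.random.default_rng(5))
        b = decoding.label_shuffle_null(feat, n=30, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.samples, b.samples)


@pytest.fixture(scope="module")
def reward_bundles():
    """Two reward-cell-only sessions differing only in the planted lead."""
    out = {}
    for lead in (0.0, 1.0):
        fx = PlantedEffects(
            n_neurons=30, frac_direction=0.0, frac_speed=0.0,
            frac_reward=0.5, frac_expected=0.0,
            reward_onset_lead_s_by_stage={s: lead for s in trial_world.STAGES})
        cfg = StageConfig.for_stage("T2")
        bundle = trial_world.simulate_session(cfg, 80, fx, seed=200)
        em = events.estimate_events(bundle.fluorescence, bundle.frame_rate_hz)
        out[lead] = (bundle, em.s_hat)
    return out


class TestCrossTemporal:
    def test_train_equals_test_window_recovers_cv_accuracy(self, reward_bundles):
        bundle, ev = reward_bundles[1.0]
        y = decoding.labels_from_trials(bundle.trials, "hit_vs_nonhit")
        ct = decoding.cross_temporal(ev, bundle.trials, y, "report",
                                     bundle.frame_rate_hz, n_null=50,
                                     rng=np.random.default_rng(1))
        feat = decoding.window_features(ev, bundle.trials, "report", y=y,
                                        frame_rate_hz=bundle.frame_rate_hz)
        plain = decoding.fit_decoder(feat, rng=np.random.default_rng(1))
        tl = ct.timeline
        in_report = ct.test_starts_s >= tl.report_start_s
        assert ct.accuracy[in_report].max() == pytest.approx(plain.accuracy, abs=0.1)

    def test_onset_tracks_planted_lead(self, reward_bundles):
        onsets = {}
        for lead, (bundle, ev) in reward_bundles.items():
            y = decoding.labels_from_trials(bundle.trials, "hit_vs_nonhit")
            ct = decoding.cross_temporal(ev, bundle.trials, y, "report",
                                         bundle.frame_rate_hz, n_null=500,
                                         rng=np.random.default_rng(2))
            onsets[lead] = decoding.decodable_onset(ct)
        assert onsets[0.0] is not None and onsets[1.0] is not None
        # a 1.0 s lead moves the onset ~1.0 s earlier
        assert onsets[0.0] - onsets[1.0] == pytest.approx(1.0, abs=0.25)

    def test_no_onset_without_signal(self):
        fx = PlantedEffects(n_neurons=20, frac_direction=0, frac_speed=0,
                            frac_reward=0, frac_expected=0)
        bundle = trial_world.simulate_session(StageConfig.for_stage("T2"),
                                              60, fx, seed=201)
        em = events.estimate_events(bundle.fluorescence, bundle.frame_rate_hz)
        y = decoding.labels_from_trials(bundle.trials, "hit_vs_nonhit")
        ct = decoding.cross_temporal(em.s_hat, bundle.trials, y, "report",
                                     bundle.frame_rate_hz, n_null=200,
                                     rng=np.random.default_rng(3))
        tl = ct.timeline
        in_span = ct.test_starts_s >= tl.test_start_s
        # weight-shuffled nulls should swallow nearly every window
        assert ct.sig_above[in_span].mean() < 0.3

    def test_sign_flip_gives_below_chance_report_accuracy(self):
        fx = PlantedEffects(n_neurons=30, frac_direction=0.0, frac_speed=0.0,
                            frac_reward=0.0, frac_expected=0.5,
                            expected_sign_flip=True)
        bundle = trial_world.simulate_session(StageConfig.for_stage("T3"),
                                              80, fx, seed=202)
        em = events.estimate_events(bundle.fluorescence, bundle.frame_rate_hz)
        y = decoding.labels_from_trials(bundle.trials, "hit_vs_nonhit")
        ct = decoding.cross_temporal(em.s_hat, bundle.trials, y, "pre_stim",
                                     bundle.frame_rate_hz, n_null=200,
                                     rng=np.random.default_rng(4))
        tl = ct.timeline
        in_report = ct.test_starts_s >= tl.report_start_s
        assert ct.sig_below[in_report].any()
        assert ct.accuracy[in_report].min() < 0.5


class TestCrossSession:
    def test_same_session_equals_within_session(self, reward_bundles):
        bundle, ev = reward_bundles[1.0]
        y = decoding.labels_from_trials(bundle.trials, "hit_vs_nonhit")
        feat = decoding.window_features(ev, bundle.trials, "report", y=y,
                                        frame_rate_hz=bundle.frame_rate_hz)
        model = decoding.fit_decoder(feat, rng=np.random.default_rng(0))
        acc, _ = decoding.cross_session(model, ev, bundle.trials, y, "report",
                                        bundle.frame_rate_hz, n_null=50)
        assert acc >= model.accuracy - 0.05

    def test_stable_code_transfers_and_fresh_code_does_not(self):
        fx = PlantedEffects(n_neurons=30)
        cfg = StageConfig.for_stage("T2")
        b1 = trial_world.simulate_session(cfg, 80, fx, seed=300)
        b2 = trial_world.simulate_session(cfg, 80, fx, seed=301)  # same roles
        fx3 = PlantedEffects(n_neurons=30, seed=77)               # re-drawn roles
        b3 = trial_world.simulate_session(cfg, 80, fx3, seed=302)
        evs = {k: events.estimate_events(b.fluorescence, b.frame_rate_hz).s_hat
               for k, b in (("b1", b1), ("b2", b2), ("b3", b3))}
        y1 = decoding.labels_from_trials(b1.trials, "hit_vs_nonhit")
        feat = decoding.window_features(evs["b1"], b1.trials, "report", y=y1,
                                        frame_rate_hz=b1.frame_rate_hz)
        model = decoding.fit_decoder(feat, rng=np.random.default_rng(0))
        y2 = decoding.labels_from_trials(b2.trials, "hit_vs_nonhit")
        acc2, null2 = decoding.cross_session(model, evs["b2"], b2.trials, y2,
                                             "report", b2.frame_rate_hz, n_null=200)
        assert acc2 > null2.pct95
        y3 = decoding.labels_from_trials(b3.trials, "hit_vs_nonhit")
        acc3, _ = decoding.cross_session(model, evs["b3"], b3.trials, y3,
                                         "report", b3.frame_rate_hz, n_null=200)
        assert acc3 < acc2

    def test_neuron_mismatch_rejected(self, reward_bundles):
        bundle, ev = reward_bundles[0.0]
        y = decoding.labels_from_trials(bundle.trials, "hit_vs_nonhit")
        feat = decoding.window_features(ev, bundle.trials, "report", y=y,
                                        frame_rate_hz=bundle.frame_rate_hz)
        model = decoding.fit_decoder(feat, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            decoding.cross_session(model, ev[:-3], bundle.trials, y, "report",
                                   bundle.frame_rate_hz)


@pytest.fixture(scope="module")
def t3_bundle():
    fx = PlantedEffects(n_neurons=30)
    bundle = trial_world.simulate_session(StageConfig.for_stage("T3"),
                                          120, fx, seed=400)
    ev = events.estimate_events(bundle.fluorescence,
                                bundle.frame_rate_hz).s_hat
    return bundle, ev


class TestCrossCondition:

    def test_shared_code_generalizes(self, t3_bundle):
        bundle, ev = t3_bundle
        res = decoding.cross_condition(ev, bundle.trials, "AP",
                                       bundle.frame_rate_hz, n_null=50,
                                       rng=np.random.default_rng(0))
        assert res["cross_acc_test_end"] == pytest.approx(
            res["same_acc_test_end"], abs=0.15)

    def test_missing_pa_rejected(self):
        fx = PlantedEffects(n_neurons=12)
        bundle = trial_world.simulate_session(StageConfig.for_stage("T2"),
                                              40, fx, seed=401)
        ev = bundle.ground_truth_spikes
        with pytest.raises(ValueError):
            decoding.cross_condition(ev, bundle.trials, "AP",
                                     bundle.frame_rate_hz)


class TestSignificantWeights:
    def test_null_calibration_flags_about_ten_percent(self):
        feat = make_features(n=80, p=40, signal=0.0, seed=9)
        mask = decoding.significant_weights(feat, n=200,
                                            rng=np.random.default_rng(0))
        assert mask.shape == (40,)
        assert mask.mean() < 0.3

    def test_tuned_neuron_flagged(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 40)
        X = rng.normal(size=(80, 10))
        X[y == 1, 0] += 3.0
        feat = LabeledFeatures(X=decoding.zscore_columns(X), y=y)
        mask = decoding.significant_weights(feat, n=200,
                                            rng=np.random.default_rng(1))
        assert mask[0]


class TestProjection:
    def test_zero_weight_model_gives_flat_bias(self, small_bundle, small_events):
        model = decoding.DecoderModel(weights=np.zeros(small_events.shape[0]),
                                      bias=0.7, accuracy=0.5)
        traj = decoding.project_decision_variable(
            small_events, small_bundle.trials, model,
            small_bundle.frame_rate_hz)
        for cond in ("hit", "CR"):
            np.testing.assert_allclose(traj[cond], 0.7, atol=1e-12)

    def test_sign_flip_trajectories_cross(self):
        fx = PlantedEffects(n_neurons=30, expected_sign_flip=True)
        bundle = trial_world.simulate_session(StageConfig.for_stage("T3"),
                                              100, fx, seed=500)
        ev = events.estimate_events(bundle.fluorescence,
                                    bundle.frame_rate_hz).s_hat
        y = decoding.labels_from_trials(bundle.trials, "hit_vs_nonhit")
        feat = decoding.window_features(ev, bundle.trials, "pre_stim", y=y,
                                        frame_rate_hz=bundle.frame_rate_hz)
        model = decoding.fit_decoder(feat, rng=np.random.default_rng(0))
        traj = decoding.project_decision_variable(ev, bundle.trials, model,
                                                  bundle.frame_rate_hz)
        tl = decoding.Timeline.from_trials(bundle.trials, bundle.frame_rate_hz)
        t = traj["time_s"]
        pre = t < tl.pre_s
        rep = t >= tl.report_start_s
        sep_pre = np.nanmean(traj["hit"][pre] - traj["CR"][pre])
        sep_rep = np.nanmean(traj["hit"][rep] - traj["CR"][rep])
        assert sep_pre > 0
        assert sep_rep < 0  # preference reverses at report


class TestPerformanceCorrelation:
    def test_perfect_and_anti_correlation(self):
        r, _ = decoding.performance_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        r, _ = decoding.performance_correlation([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        x = [0.5, 0.6, 0.7, 0.9]
        y = [1.0, 1.2, 1.1, 1.9]
        r, p = decoding.performance_correlation(x, y)
        xm, ym = np.mean(x), np.mean(y)
        r_hand = np.sum((np.array(x) - xm) * (np.array(y) - ym)) / np.sqrt(
            np.sum((np.array(x) - xm) ** 2) * np.sum((np.array(y) - ym) ** 2))
        assert r == pytest.approx(r_hand)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            decoding.performance_correlation([1, 1, 1], [1, 2, 3])
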