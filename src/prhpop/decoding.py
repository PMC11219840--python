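"""Calibrated linear population decoding.

Session decoders are maximum-margin linear classifiers (SVM) on single-trial
population vectors: per neuron, event estimates are averaged over a trial
window and z-scored across trials.  Accuracy comes from 10-fold stratified
cross-validation; imbalanced labels are handled by resampling the minority
class in each training split (repeated 100 times).  Significance is assessed
against label-shuffle nulls (training labels permuted before fitting, 1000
repetitions, 95th/5th percentile bands).  Cross-temporal decoders train on one
trial period (or a sliding 1000 ms window) and test on sliding 300 ms windows,
with significance from weight-shuffle nulls; the decodable onset is the first
significant window across the test and report periods.  Cross-session and
cross-condition (AP vs PA) decoders, per-neuron weight significance, and the
projection of population activity onto the decision-variable axis complete
the suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

PERIODS = ("pre_stim", "sample", "delay", "test", "report")
DEFAULT_C = 1.0
TEST_WIDTH_S = 0.3
TEST_STEP_S = 0.1
TRAIN_WIDTH_S = 1.0
TRAIN_STEP_S = 0.25


@dataclass
class LabeledFeatures:
    """Trials x neurons window-averaged, z-scored features with binary labels."""

    X: np.ndarray
    y: np.ndarray
    window: object = None
    trial_ids: np.ndarray = None

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y)
        if len(np.unique(self.y)) != 2:
            raise ValueError("labels must have exactly two classes")
        if self.trial_ids is None:
            self.trial_ids = np.arange(len(self.y))


@dataclass
class DecoderModel:
    weights: np.ndarray
    bias: float
    accuracy: float
    train_window: object = None
    n_resamples: int = 1
    classes: tuple = (0, 1)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties at exactly 0 go to the negative class
        return (self.decision_values(X) > 0).astype(int)


@dataclass
class NullDistribution:
    samples: np.ndarray
    kind: str = "label_shuffle"

    @property
    def pct95(self) -> float:
        return float(np.percentile(self.samples, 95))

    @property
    def pct5(self) -> float:
        return float(np.percentile(self.samples, 5))


@dataclass
class CrossTemporalResult:
    train_window: object
    test_starts_s: np.ndarray       # window start times on the canonical axis
    accuracy: np.ndarray
    sig_above: np.ndarray
    sig_below: np.ndarray
    pct95: np.ndarray
    pct5: np.ndarray
    timeline: "Timeline" = None
    #: n_null x n_windows null accuracies, one shared weight permutation per
    #: row, enabling max-statistic (familywise) corrections across windows
    null_samples: np.ndarray = None


def zscore_columns(X: np.ndarray) -> np.ndarray:
    """Z-score each column across trials; zero-variance columns map to 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = (X - mu) / np.where(sd > 0, sd, 1.0)
    out[:, sd == 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# canonical within-trial timeline and window features


@dataclass
class Timeline:
    """Canonical within-trial time axis shared across trials.

    Trials are aligned at trial start for the pre-stimulus and sample periods
    and at test onset for the test and report periods; the delay segment uses
    the session's minimum delay so that the axis is valid for every trial.
    """

    frame_rate_hz: float
    pre_s: float
    sample_s: float
    delay_s: float
    test_s: float
    report_s: float

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, frame_rate_hz: float) -> "Timeline":
        fr = frame_rate_hz
        t0 = trials.iloc[0]
        return cls(
            frame_rate_hz=fr,
            pre_s=(t0.pre_stim_end - t0.pre_stim_start) / fr,
            sample_s=(t0.sample_end - t0.sample_start) / fr,
            delay_s=float((trials.delay_end - trials.delay_start).min()) / fr,
            test_s=(t0.test_end - t0.test_start) / fr,
            report_s=(t0.report_end - t0.report_start) / fr,
        )

    @property
    def total_s(self) -> float:
        return self.pre_s + self.sample_s + self.delay_s + self.test_s + self.report_s

    @property
    def test_start_s(self) -> float:
        return self.pre_s + self.sample_s + self.delay_s

    @property
    def report_start_s(self) -> float:
        return self.test_start_s + self.test_s

    def period_window(self, period: str) -> tuple:
        starts = {
            "pre_stim": 0.0,
            "sample": self.pre_s,
            "delay": self.pre_s + self.sample_s,
            "test": self.test_start_s,
            "report": self.report_start_s,
        }
        widths = {"pre_stim": self.pre_s, "sample": self.sample_s,
                  "delay": self.delay_s, "test": self.test_s, "report": self.report_s}
        return starts[period], widths[period]

    def frames_for(self, trial: pd.Series, start_s: float, width_s: float) -> np.ndarray:
        """Frame indices of a canonical window [start, start+width) in a trial.

        Windows whose start falls before test onset are anchored at trial
        start; later windows are anchored at the trial's own test onset, so
        variable delays do not shift test/report activity.  Frames past the
        trial's report end are truncated.
        """
        fr = self.frame_rate_hz
        a = int(np.floor(start_s * fr))
        b = int(np.floor((start_s + width_s) * fr))
        split = int(np.floor(self.test_start_s * fr))
        pre_anchor = int(trial.pre_stim_start)
        test_anchor = int(trial.test_start)
        frames = []
        for k in range(a, max(b, a + 1)):
            if k < split:
                f = pre_anchor + k
                if f < int(trial.test_start):
                    frames.append(f)
            else:
                f = test_anchor + (k - split)
                if f < int(trial.report_end):
                    frames.append(f)
        return np.asarray(frames, dtype=int)


def resolve_window(window, timeline: Timeline) -> tuple:
    """A window is a period name or an explicit (start_s, width_s) pair."""
    if isinstance(window, str):
        return timeline.period_window(window)
    start_s, width_s = window
    return float(start_s), float(width_s)


def window_features(ev: np.ndarray, trials: pd.DataFrame, window,
                    y: Optional[np.ndarray] = None,
                    frame_rate_hz: float = None,
                    timeline: Optional[Timeline] = None) -> LabeledFeatures:
    """Average events over a trial window per neuron, then z-score across trials."""
    if timeline is None:
        timeline = Timeline.from_trials(trials, frame_rate_hz)
    start_s, width_s = resolve_window(window, timeline)
    if width_s <= 0:
        raise ValueError("empty window")
    fr = timeline.frame_rate_hz
    a = int(np.floor(start_s * fr))
    b = max(int(np.floor((start_s + width_s) * fr)), a + 1)
    split = int(np.floor(timeline.test_start_s * fr))
    k = np.arange(a, b)
    pre_anchor = trials["pre_stim_start"].to_numpy(dtype=int)[:, None]
    test_anchor = trials["test_start"].to_numpy(dtype=int)[:, None]
    report_end = trials["report_end"].to_numpy(dtype=int)[:, None]
    early = k < split
    frames = np.where(early, pre_anchor + k, test_anchor + (k - split))
    valid = np.where(early, frames < test_anchor, frames < report_end)
    n_valid = valid.sum(axis=1)
    if (n_valid == 0).any():
        raise ValueError(f"window ({start_s:.2f}, {width_s:.2f}) empty for "
                         f"{int((n_valid == 0).sum())} trials")
    frames = np.clip(frames, 0, ev.shape[1] - 1)
    vals = ev[:, frames]                       # neurons x trials x window
    X = ((vals * valid[None]).sum(axis=2) / n_valid[None]).T
    X = zscore_columns(X)
    if y is None:
        y = np.zeros(len(trials))
        y[: len(y) // 2] = 1  # placeholder labels; callers normally supply y
    return LabeledFeatures(X=X, y=np.asarray(y), window=(start_s, width_s),
                           trial_ids=trials["trial_id"].to_numpy())


def labels_from_trials(trials: pd.DataFrame, label: str) -> np.ndarray:
    """Standard binary labelings used throughout the analyses."""
    if label == "direction":
        return (trials["sample_dir"] == "A").to_numpy().astype(int)
    if label == "test_direction":
        return (trials["test_dir"] == "A").to_numpy().astype(int)
    if label == "speed":
        return (trials["speed"] == "slow").to_numpy().astype(int)
    if label == "hit_vs_nonhit":
        return (trials["outcome"] == "hit").to_numpy().astype(int)
    if label == "cr_vs_noncr":
        return (trials["outcome"] == "CR").to_numpy().astype(int)
    if label == "correct_vs_error":
        return trials["outcome"].isin(["hit", "CR"]).to_numpy().astype(int)
    raise ValueError(f"unknown label {label!r}")


# ---------------------------------------------------------------------------
# decoder fits


def _svm(C: float = DEFAULT_C) -> LinearSVC:
    # large intercept_scaling leaves the bias effectively unpenalized, so it
    # is never smuggled into near-constant feature columns
    return LinearSVC(C=C, loss="squared_hinge", dual=False, max_iter=5000,
                     tol=1e-5, intercept_scaling=100.0)


def _safe_folds(y: np.ndarray, folds: int) -> int:
    _, counts = np.unique(y, return_counts=True)
    return int(min(folds, counts.min()))


def fit_decoder(feat: LabeledFeatures, folds: int = 10, C: float = DEFAULT_C,
                rng: Optional[np.random.Generator] = None) -> DecoderModel:
    """Max-margin linear decoder with stratified k-fold CV accuracy.

    The reported accuracy is the mean held-out accuracy across folds; the
    returned weights are refit on all trials.
    """
    X, y = feat.X, feat.y
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need two classes")
    yb = (y == classes[1]).astype(int)
    k = _safe_folds(yb, folds)
    if k < 2:
        raise ValueError("need at least 2 trials per class for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2**31)) if rng is not None else 0)
    accs = []
    for tr_idx, te_idx in skf.split(X, yb):
        clf = _svm(C).fit(X[tr_idx], yb[tr_idx])
        accs.append(np.mean(clf.predict(X[te_idx]) == yb[te_idx]))
    clf = _svm(C).fit(X, yb)
    return DecoderModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]),
                        accuracy=float(np.mean(accs)), train_window=feat.window,
                        classes=tuple(classes))


def _balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean of per-class accuracies; chance is 0.5 at any class imbalance."""
    accs = [np.mean(pred[truth == c] == c) for c in (0, 1) if np.any(truth == c)]
    return float(np.mean(accs))


def fit_decoder_resampled(feat: LabeledFeatures, folds: int = 10,
                          n_resamples: int = 100, C: float = DEFAULT_C,
                          rng: Optional[np.random.Generator] = None) -> DecoderModel:
    """Decoder for imbalanced labels: upsample the training minority class.

    In each training split the minority class is resampled with replacement to
    match the majority count; the whole CV is repeated ``n_resamples`` times.
    Held-out performance is the balanced accuracy (mean of per-class
    accuracies), so chance stays at 0.5 no matter how rare the minority
    class is.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X, y = feat.X, feat.y
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    yb = (y == classes[1]).astype(int)
    k = _safe_folds(yb, folds)
    if k < 2:
        raise ValueError("need at least 2 trials per class")
    accs = []
    for _ in range(n_resamples):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for tr_idx, te_idx in skf.split(X, yb):
            Xb, ybb = _balance(X[tr_idx], yb[tr_idx], rng)
            clf = _svm(C).fit(Xb, ybb)
            accs.append(_balanced_accuracy(clf.predict(X[te_idx]), yb[te_idx]))
    clf = _svm(C).fit(*_balance(X, yb, rng))
    return DecoderModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]),
                        accuracy=float(np.mean(accs)), train_window=feat.window,
                        n_resamples=n_resamples, classes=tuple(classes))


def _balance(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == n1:
        return X, y
    minority = 1 if n1 < n0 else 0
    idx_min = np.nonzero(y == minority)[0]
    extra = rng.choice(idx_min, size=abs(n0 - n1), replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx]


def label_shuffle_null(feat: LabeledFeatures, folds: int = 10, n: int = 1000,
                       C: float = DEFAULT_C, resample: bool = False,
                       rng: Optional[np.random.Generator] = None) -> NullDistribution:
    """Null accuracies from permuting training labels before classification.

    Within each CV fold the training labels are shuffled and the fit is
    evaluated against the held-out trials' true labels.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X, y = feat.X, feat.y
    classes = np.unique(y)
    yb = (y == classes[1]).astype(int)
    k = _safe_folds(yb, folds)
    samples = np.empty(n)
    for j in range(n):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        accs = []
        for tr_idx, te_idx in skf.split(X, yb):
            y_tr = rng.permutation(yb[tr_idx])
            if len(np.unique(y_tr)) < 2:
                accs.append(0.5)
                continue
            Xf, yf = (X[tr_idx], y_tr)
            if resample:
                Xf, yf = _balance(Xf, yf, rng)
            clf = _svm(C).fit(Xf, yf)
            pred = clf.predict(X[te_idx])
            if resample:
                accs.append(_balanced_accuracy(pred, yb[te_idx]))
            else:
                accs.append(np.mean(pred == yb[te_idx]))
        samples[j] = np.mean(accs)
    return NullDistribution(samples=samples, kind="label_shuffle")


# ---------------------------------------------------------------------------
# cross-temporal decoding


def _weight_shuffle_accuracy(model: DecoderModel, X: np.ndarray, yb: np.ndarray,
                             n: int, rng: np.random.Generator) -> np.ndarray:
    """Accuracies of decoders whose weight vector is permuted across neurons.

    The bias is kept (not refit), matching a pure read-out shuffle.
    """
    W = np.empty((X.shape[1], n))
    for j in range(n):
        W[:, j] = rng.permutation(model.weights)
    pred = (X @ W + model.bias) > 0
    return (pred == yb[:, None]).mean(axis=0)


def sliding_test_windows(timeline: Timeline, width_s: float = TEST_WIDTH_S,
                         step_s: float = TEST_STEP_S) -> np.ndarray:
    last = timeline.total_s - width_s
    return np.arange(0.0, last + 1e-9, step_s)


def cross_temporal(ev: np.ndarray, trials: pd.DataFrame, y: np.ndarray,
                   train_window, frame_rate_hz: float,
                   test_width_s: float = TEST_WIDTH_S,
                   step_s: float = TEST_STEP_S, folds: int = 10,
                   n_null: int = 1000, C: float = DEFAULT_C,
                   resample: bool = False,
                   rng: Optional[np.random.Generator] = None,
                   train_trials_mask: Optional[np.ndarray] = None,
                   test_trials_mask: Optional[np.ndarray] = None) -> CrossTemporalResult:
    """Train on one window, test on sliding 300 ms windows across the trial.

    With the default masks, accuracy at each test window is 10-fold
    cross-validated: the decoder is fit on the train-window features of the
    training folds and applied to the test-window features of held-out trials.
    Significance per window comes from a weight-shuffle null: each fold
    model's weight vector is permuted across neurons (``n_null`` shared
    permutations) and scored under the same held-out scheme as the actual
    accuracy, giving 95th/5th percentile bands with matched sampling noise.
    With explicit trial masks a single frozen model is used and the null is
    evaluated on the test-mask trials.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    timeline = Timeline.from_trials(trials, frame_rate_hz)
    y = np.asarray(y)
    classes = np.unique(y)
    yb = (y == classes[-1]).astype(int)

    feat_train = window_features(ev, trials, train_window, y=yb,
                                 frame_rate_hz=frame_rate_hz, timeline=timeline)
    starts = sliding_test_windows(timeline, test_width_s, step_s)
    feats_test = [window_features(ev, trials, (s, test_width_s), y=yb,
                                  frame_rate_hz=frame_rate_hz, timeline=timeline)
                  for s in starts]

    if train_trials_mask is None and test_trials_mask is None:
        k = _safe_folds(yb, folds)
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        splits = list(skf.split(feat_train.X, yb))
        acc = np.zeros(len(starts))
        fold_models = []
        for tr_idx, te_idx in splits:
            Xf, yf = feat_train.X[tr_idx], yb[tr_idx]
            if resample:
                Xf, yf = _balance(Xf, yf, rng)
            clf = _svm(C).fit(Xf, yf)
            fold_models.append((clf.coef_.ravel().copy(),
                                float(clf.intercept_[0]), te_idx))
            for wi, ft in enumerate(feats_test):
                acc[wi] += np.mean(clf.predict(ft.X[te_idx]) == yb[te_idx])
        acc /= len(splits)
        full = _svm(C).fit(*( _balance(feat_train.X, yb, rng) if resample
                              else (feat_train.X, yb)))
        model = DecoderModel(weights=full.coef_.ravel().copy(),
                             bias=float(full.intercept_[0]), accuracy=float("nan"))

        # null: permute each fold model's weights with the same permutations
        # and score with the same held-out scheme as the actual accuracy
        n_neurons = feat_train.X.shape[1]
        perms = np.stack([rng.permutation(n_neurons) for _ in range(n_null)])
        nulls = np.zeros((n_null, len(starts)))
        for wi, ft in enumerate(feats_test):
            null_acc = np.zeros(n_null)
            for w, b, te_idx in fold_models:
                W = w[perms].T                      # neurons x n_null
                pred = (ft.X[te_idx] @ W + b) > 0
                null_acc += (pred == yb[te_idx, None]).mean(axis=0)
            nulls[:, wi] = null_acc / len(fold_models)
        pct95 = np.percentile(nulls, 95, axis=0)
        pct5 = np.percentile(nulls, 5, axis=0)
        return CrossTemporalResult(
            train_window=train_window, test_starts_s=starts, accuracy=acc,
            sig_above=acc > pct95, sig_below=acc < pct5,
            pct95=pct95, pct5=pct5, timeline=timeline, null_samples=nulls)
    else:
        tr_mask = (np.ones(len(yb), bool) if train_trials_mask is None
                   else np.asarray(train_trials_mask, bool))
        te_mask = (np.ones(len(yb), bool) if test_trials_mask is None
                   else np.asarray(test_trials_mask, bool))
        Xf, yf = feat_train.X[tr_mask], yb[tr_mask]
        if resample:
            Xf, yf = _balance(Xf, yf, rng)
        clf = _svm(C).fit(Xf, yf)
        model = DecoderModel(weights=clf.coef_.ravel().copy(),
                             bias=float(clf.intercept_[0]), accuracy=float("nan"))
        acc = np.array([np.mean(clf.predict(ft.X[te_mask]) == yb[te_mask])
                        for ft in feats_test])
        eval_idx = np.nonzero(te_mask)[0]

        perms = np.stack([rng.permutation(len(model.weights))
                          for _ in range(n_null)])
        W = model.weights[perms].T
        nulls = np.zeros((n_null, len(starts)))
        for wi, ft in enumerate(feats_test):
            pred = (ft.X[eval_idx] @ W + model.bias) > 0
            nulls[:, wi] = (pred == yb[eval_idx, None]).mean(axis=0)
        pct95 = np.percentile(nulls, 95, axis=0)
        pct5 = np.percentile(nulls, 5, axis=0)
    return CrossTemporalResult(
        train_window=train_window, test_starts_s=starts, accuracy=acc,
        sig_above=acc > pct95, sig_below=acc < pct5,
        pct95=pct95, pct5=pct5, timeline=timeline, null_samples=nulls)


def decodable_onset(ct: CrossTemporalResult, corrected: bool = True,
                    min_consecutive: int = 1) -> Optional[float]:
    """Earliest significant window within the test + report span.

    By default significance is assessed against a max-statistic threshold:
    the 95th percentile of the *maximum* null accuracy over the span (one
    shared weight permutation per null sample), which controls the
    familywise false-onset rate at 5% across the span — the per-window bands
    admit ~5% false flags per window, which with ~10+ pre-signal windows
    would corrupt the "first significant" reading in a sizeable fraction of
    sessions.  Set ``corrected=False`` for the literal per-window bands, and
    ``min_consecutive`` to demand a run of consecutive significant windows.
    Returns the onset in seconds on the canonical trial axis, or None.
    """
    tl = ct.timeline
    in_span = (ct.test_starts_s >= tl.test_start_s - 1e-9) & \
              (ct.test_starts_s < tl.total_s)
    if corrected:
        if ct.null_samples is None:
            raise ValueError("corrected onset needs stored null samples")
        max_null = ct.null_samples[:, in_span].max(axis=1)
        thr = np.percentile(max_null, 95)
        sig = in_span & (ct.accuracy > thr)
    else:
        sig = in_span & ct.sig_above
    count = 0
    for i, flag in enumerate(sig):
        count = count + 1 if flag else 0
        if count >= min_consecutive:
            return float(ct.test_starts_s[i - min_consecutive + 1])
    return None


def cross_session(model: DecoderModel, ev_other: np.ndarray,
                  trials_other: pd.DataFrame, y_other: np.ndarray, window,
                  frame_rate_hz: float, n_null: int = 1000,
                  rng: Optional[np.random.Generator] = None):
    """Apply a frozen decoder to another session of the same neurons.

    Features are recomputed (and z-scored) within the target session; returns
    (accuracy, weight-shuffle NullDistribution).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if ev_other.shape[0] != len(model.weights):
        raise ValueError("neuron count differs between sessions")
    y_other = np.asarray(y_other)
    classes = np.unique(y_other)
    yb = (y_other == classes[-1]).astype(int)
    feat = window_features(ev_other, trials_other, window, y=yb,
                           frame_rate_hz=frame_rate_hz)
    acc = float(np.mean(model.predict(feat.X) == yb))
    null = _weight_shuffle_accuracy(model, feat.X, yb, n_null, rng)
    return acc, NullDistribution(samples=null, kind="weight_shuffle")


def cross_condition(ev: np.ndarray, trials: pd.DataFrame, train_cond: str,
                    frame_rate_hz: float, n_null: int = 200,
                    rng: Optional[np.random.Generator] = None) -> dict:
    """Train a reward decoder on one nonmatch condition, test on the other.

    Nonmatch trials are split by stimulus condition (AP vs PA) into train and
    test sets; match trials are split randomly between them.  The decoder is
    trained on report-period activity, hit vs non-hit, and evaluated
    cross-temporally on the held-out condition; the summary statistic is the
    accuracy of the 300 ms window ending at the end of the test period.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if train_cond not in ("AP", "PA"):
        raise ValueError("train_cond must be 'AP' or 'PA'")
    sample = trials["sample_dir"].to_numpy()
    nonmatch = trials["category"].to_numpy() == "nonmatch"
    is_AP = nonmatch & (sample == "A")
    is_PA = nonmatch & (sample == "P")
    if not is_PA.any() or not is_AP.any():
        raise ValueError("both AP and PA nonmatch trials are required")
    train_nm = is_AP if train_cond == "AP" else is_PA
    test_nm = is_PA if train_cond == "AP" else is_AP
    match_idx = np.nonzero(~nonmatch)[0]
    perm = rng.permutation(match_idx)
    train_match = np.zeros(len(trials), bool)
    test_match = np.zeros(len(trials), bool)
    train_match[perm[: len(perm) // 2]] = True
    test_match[perm[len(perm) // 2:]] = True
    train_mask = train_nm | train_match
    test_mask = test_nm | test_match

    y = labels_from_trials(trials, "hit_vs_nonhit")
    ct_same = cross_temporal(ev, trials, y, "report", frame_rate_hz,
                             n_null=n_null, rng=rng,
                             train_trials_mask=train_mask,
                             test_trials_mask=train_mask)
    ct_cross = cross_temporal(ev, trials, y, "report", frame_rate_hz,
                              n_null=n_null, rng=rng,
                              train_trials_mask=train_mask,
                              test_trials_mask=test_mask)

    tl = ct_cross.timeline
    target = tl.report_start_s - TEST_WIDTH_S  # window ending at test-period end
    wi = int(np.argmin(np.abs(ct_cross.test_starts_s - target)))
    return {
        "same_condition": ct_same,
        "cross_condition": ct_cross,
        "same_acc_test_end": float(ct_same.accuracy[wi]),
        "cross_acc_test_end": float(ct_cross.accuracy[wi]),
        "window_start_s": float(ct_cross.test_starts_s[wi]),
    }


def significant_weights(feat: LabeledFeatures, n: int = 1000, folds: int = 10,
                        C: float = DEFAULT_C,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-neuron significance of decoder weights under label shuffling.

    A neuron is flagged when its full-fit weight falls above the 95th or below
    the 5th percentile of its own label-shuffled weight distribution.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    model = fit_decoder(feat, folds=folds, C=C, rng=rng)
    classes = np.unique(feat.y)
    yb = (feat.y == classes[-1]).astype(int)
    W = np.empty((n, feat.X.shape[1]))
    for j in range(n):
        y_sh = rng.permutation(yb)
        if len(np.unique(y_sh)) < 2:  # cannot happen with two classes present
            W[j] = 0.0
            continue
        W[j] = _svm(C).fit(feat.X, y_sh).coef_.ravel()
    hi = np.percentile(W, 95, axis=0)
    lo = np.percentile(W, 5, axis=0)
    return (model.weights > hi) | (model.weights < lo)


def project_decision_variable(ev: np.ndarray, trials: pd.DataFrame,
                              model: DecoderModel, frame_rate_hz: float,
                              step_s: float = TEST_STEP_S,
                              width_s: float = TEST_WIDTH_S) -> dict:
    """Mean projection w.x(t) + b per outcome class along the trial.

    Activity in each sliding window is z-scored across trials (as for
    decoding) and projected on the decision-variable axis; trajectories are
    averaged within each of the four outcome classes.
    """
    timeline = Timeline.from_trials(trials, frame_rate_hz)
    starts = sliding_test_windows(timeline, width_s, step_s)
    proj = np.empty((len(trials), len(starts)))
    for wi, s in enumerate(starts):
        ft = window_features(ev, trials, (s, width_s), y=None,
                             frame_rate_hz=frame_rate_hz, timeline=timeline)
        proj[:, wi] = model.decision_values(ft.X)
    outcome = trials["outcome"].to_numpy()
    out = {"time_s": starts}
    for cond in ("hit", "miss", "FA", "CR"):
        mask = outcome == cond
        out[cond] = proj[mask].mean(axis=0) if mask.any() else np.full(len(starts), np.nan)
    return out


def performance_correlation(decoder_acc: Sequence[float],
                            dprime: Sequence[float]) -> tuple:
    """Pearson correlation between per-session decoder accuracy and d'."""
    a = np.asarray(decoder_acc, float)
    d = np.asarray(dprime, float)
    if len(a) != len(d) or len(a) < 3:
        raise ValueError("need equal-length vectors of at least 3 sessions")
    if a.std() == 0 or d.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = pearsonr(a, d)
    return float(r), float(p)
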