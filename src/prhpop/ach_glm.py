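"""Normal GLM of bulk acetylcholine signals with task-variable covariates.

The trace is modeled as y_t = sum_i w_i x_i(t) with an identity link and
Gaussian noise.  Covariates are boxcars for the pre-stimulus period, each
stimulus direction (sample + test frames of that direction), the 300 ms
post-reward window, and the post-trial period, plus lick trains convolved
with a 10-sample Gaussian kernel and split into pre-reward and post-reward
licking.  Fits use an L1 penalty path (6 values, 4-fold CV).  Factor
importance is the AIC increase when a task factor's covariates are removed:

    AIC = 2k + deviance,   dAIC = AIC_partial - AIC_full

with deviance the residual sum of squares at unit dispersion (a fixed
Gaussian constant, so AIC differences between nested fits are well defined)
and k the number of nonzero parameters including the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy.signal.windows import gaussian as gaussian_window
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

COVARIATES = ["pre_stimulus", "stim_dir_anterior", "stim_dir_posterior",
              "reward", "lick_pre", "lick_post", "post_trial"]

#: covariate -> task factor; the two direction covariates share one factor
DEFAULT_FACTORS = {
    "pre_stimulus": "pre_stimulus",
    "stim_dir_anterior": "stimulus_direction",
    "stim_dir_posterior": "stimulus_direction",
    "reward": "reward",
    "lick_pre": "lick_pre",
    "lick_post": "lick_post",
    "post_trial": "post_trial",
}

REWARD_BOXCAR_S = 0.3
LICK_KERNEL_SAMPLES = 10
LICK_KERNEL_SD = 2.0


@dataclass
class DesignMatrix:
    X: np.ndarray                 # frames x covariates
    names: list
    frame_rate_hz: float

    def drop(self, names_to_drop) -> "DesignMatrix":
        keep = [i for i, n in enumerate(self.names) if n not in names_to_drop]
        return DesignMatrix(X=self.X[:, keep],
                            names=[self.names[i] for i in keep],
                            frame_rate_hz=self.frame_rate_hz)


@dataclass
class GLMFit:
    weights: np.ndarray
    intercept: float
    deviance: float
    k: int
    penalty: float
    cv_deviance: dict = field(default_factory=dict)
    names: list = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k + self.deviance


def _lick_kernel() -> np.ndarray:
    k = gaussian_window(LICK_KERNEL_SAMPLES, LICK_KERNEL_SD)
    return k / k.sum()


def build_design(trials: pd.DataFrame, frame_rate_hz: float) -> DesignMatrix:
    """Assemble the frames x covariates task design matrix."""
    n_frames = int(trials["post_end"].max())
    cols = {name: np.zeros(n_frames) for name in COVARIATES}
    n_reward = int(round(REWARD_BOXCAR_S * frame_rate_hz))
    licks_pre = np.zeros(n_frames)
    licks_post = np.zeros(n_frames)
    for _, tr in trials.iterrows():
        cols["pre_stimulus"][int(tr.pre_stim_start): int(tr.pre_stim_end)] = 1.0
        for period, d in (("sample", tr.sample_dir), ("test", tr.test_dir)):
            name = "stim_dir_anterior" if d == "A" else "stim_dir_posterior"
            cols[name][int(tr[f"{period}_start"]): int(tr[f"{period}_end"])] = 1.0
        cols["post_trial"][int(tr.post_start): int(tr.post_end)] = 1.0
        reward = tr.reward_frame
        if reward is not None and not (isinstance(reward, float) and np.isnan(reward)):
            reward = int(reward)
            cols["reward"][reward: min(reward + n_reward, n_frames)] = 1.0
        for f in (tr.lick_frames or []):
            f = int(f)
            if reward is not None and not (isinstance(reward, float) and np.isnan(reward)) \
                    and f >= int(reward):
                licks_post[f] += 1.0
            else:
                licks_pre[f] += 1.0
    kern = _lick_kernel()
    cols["lick_pre"] = np.convolve(licks_pre, kern, mode="same")
    cols["lick_post"] = np.convolve(licks_post, kern, mode="same")
    X = np.column_stack([cols[n] for n in COVARIATES])
    return DesignMatrix(X=X, names=list(COVARIATES), frame_rate_hz=frame_rate_hz)


def _deviance(y, yhat) -> float:
    return float(np.sum((y - yhat) ** 2))


def _fit_at(X, y, penalty: float):
    if penalty <= 0:
        model = LinearRegression().fit(X, y)
    else:
        # sklearn's lasso objective is (1/2n)*RSS + alpha*||w||_1
        model = Lasso(alpha=penalty, max_iter=50000, tol=1e-8).fit(X, y)
    return np.asarray(model.coef_, float).ravel(), float(model.intercept_)


def penalty_grid(X: np.ndarray, y: np.ndarray, n_penalties: int = 6,
                 decades: float = 3.0) -> np.ndarray:
    """Log-spaced L1 path from the all-zero penalty down by ``decades``."""
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max / 10**decades, n_penalties)


def fit_glm(y: np.ndarray, design: DesignMatrix, n_penalties: int = 6,
            folds: int = 4, seed: int = 0,
            count_all_params: bool = False) -> GLMFit:
    """L1-penalized Gaussian identity-link fit with CV penalty selection.

    The penalty minimizing the 4-fold CV deviance is chosen; the selected
    model is refit on all frames and its full-data deviance reported.
    ``k`` counts nonzero parameters including the intercept (or all
    parameters when ``count_all_params``).
    """
    y = np.asarray(y, float)
    X = design.X
    if X.shape[0] != len(y):
        raise ValueError("frame counts of y and design differ")
    if X.shape[1] == 0 or not np.any(X):
        log.warning("all-zero design; intercept-only fit")
        mu = y.mean()
        return GLMFit(weights=np.zeros(X.shape[1]), intercept=float(mu),
                      deviance=_deviance(y, mu), k=1, penalty=0.0,
                      names=list(design.names))
    grid = penalty_grid(X, y, n_penalties)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv = {}
    for lam in grid:
        dev = 0.0
        for tr, te in kf.split(X):
            w, b = _fit_at(X[tr], y[tr], lam)
            dev += _deviance(y[te], X[te] @ w + b)
        cv[float(lam)] = dev
    best = min(cv, key=cv.get)
    w, b = _fit_at(X, y, best)
    k = X.shape[1] + 1 if count_all_params else int(np.sum(w != 0)) + 1
    return GLMFit(weights=w, intercept=b, deviance=_deviance(y, X @ w + b),
                  k=k, penalty=best, cv_deviance=cv, names=list(design.names))


def aic(fit: GLMFit) -> float:
    """Akaike information criterion: 2k + deviance (unit-dispersion Gaussian)."""
    return fit.aic


def factor_delta_aic(y: np.ndarray, design: DesignMatrix,
                     grouping: dict = None, seed: int = 0,
                     n_penalties: int = 6, folds: int = 4) -> pd.DataFrame:
    """dAIC per task factor: refit without the factor's covariates.

    Positive dAIC means the factor carries information the rest of the model
    cannot absorb; a useless factor costs only its parameter count
    (dAIC ~ -2 per removed nonzero parameter).
    """
    grouping = DEFAULT_FACTORS if grouping is None else grouping
    missing = set(design.names) - set(grouping)
    if missing:
        raise ValueError(f"covariates without a factor: {sorted(missing)}")
    full = fit_glm(y, design, n_penalties, folds, seed)
    rows = []
    factors = sorted(set(grouping.values()))
    for factor in factors:
        drop = [n for n in design.names if grouping[n] == factor]
        partial = fit_glm(y, design.drop(drop), n_penalties, folds, seed)
        rows.append({"factor": factor, "delta_aic": partial.aic - full.aic,
                     "aic_full": full.aic, "aic_partial": partial.aic,
                     "n_removed": len(drop)})
    return pd.DataFrame(rows).sort_values("delta_aic", ascending=False,
                                          ignore_index=True)
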