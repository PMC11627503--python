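"""Model-free behavioral analyses of gamble-choice data.

Within-subject logistic regression of accept/reject choices on
prospective gains and losses,

    p(accept) = s(w0 + wG * G - wL * L),        s the logistic sigmoid,

with losses entered as positive magnitudes (note the minus sign), the
loss-aversion index lambda = log(wL / wG) (invariant to behavioral
temperature, which rescales all coefficients together), balanced
accuracy, EV-decile acceptance curves, non-overlapping 16-trial
sliding-window dynamics of loss aversion, and pooled-variance group F
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .core import GambleTrial, trials_to_arrays

__all__ = [
    "ChoiceDataset",
    "LogisticFit",
    "fit_choice_logistic",
    "loss_aversion_index",
    "balanced_accuracy",
    "sliding_window_loss_aversion",
    "ev_decile_curve",
    "group_f_test",
    "common_ev_mask",
]


@dataclass
class ChoiceDataset:
    """One subject's trials and binarized accept/reject responses.

    ``accept`` is a float array with 1 for (strongly or weakly) accept,
    0 for reject, NaN for missing responses; missing trials are excluded
    from all fits.
    """

    trials: Sequence[GambleTrial]
    accept: np.ndarray
    subject_id: str = "s0"
    group: Optional[str] = None  # "narrow" | "wide" | None

    def __post_init__(self):
        self.accept = np.asarray(self.accept, dtype=float)
        if len(self.trials) != self.accept.shape[0]:
            raise ValueError("accept vector must match the number of trials")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def arrays(self):
        gains, losses, evs, sessions = trials_to_arrays(self.trials)
        return gains, losses, evs, sessions, self.accept

    def subset(self, idx) -> "ChoiceDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ChoiceDataset(
            trials=[self.trials[i] for i in idx],
            accept=self.accept[idx],
            subject_id=self.subject_id,
            group=self.group,
        )


@dataclass
class LogisticFit:
    """Estimates of the choice logistic model (logit units per dollar)."""

    w0: float
    wG: float
    wL: float
    cov: np.ndarray
    converged: bool
    flag: Optional[str] = None  # None | "ridge" | "degenerate"
    n_obs: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def loss_aversion(self) -> float:
        return loss_aversion_index(self)


def _design(gains, losses):
    # minus sign on L: wL is the sensitivity to loss magnitude
    return np.column_stack([np.ones_like(gains), gains, -losses])


def _ridge_logistic(X, y, prior_sd: float = 10.0):
    """MAP logistic fit with an independent N(0, prior_sd^2) prior per
    coefficient; used only when plain IRLS fails (separation, degeneracy)."""

    def negloglik(beta):
        eta = X @ beta
        # log(1+exp) stable
        ll = y * eta - np.logaddexp(0.0, eta)
        return -np.sum(ll) + 0.5 * np.sum((beta / prior_sd) ** 2)

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return -X.T @ (y - p) + beta / prior_sd ** 2

    res = optimize.minimize(negloglik, np.zeros(X.shape[1]), jac=grad, method="BFGS")
    p = 1.0 / (1.0 + np.exp(-(X @ res.x)))
    W = p * (1 - p)
    H = (X * W[:, None]).T @ X + np.eye(X.shape[1]) / prior_sd ** 2
    cov = np.linalg.inv(H)
    return res.x, cov, bool(res.success)


def fit_choice_logistic(data: ChoiceDataset, prior_sd: float = 10.0,
                        min_trials: int = 10) -> LogisticFit:
    """Maximum-likelihood logistic fit via IRLS, with a weak-ridge fallback.

    Degenerate data (single response class) or perfect separation are
    fitted under a Gaussian ridge prior (sd ``prior_sd`` per coefficient)
    and flagged.  Missing responses are excluded trial-wise.
    """
    gains, losses, _, _, accept = data.arrays()
    keep = np.isfinite(accept)
    gains, losses, y = gains[keep], losses[keep], accept[keep]
    n = y.shape[0]
    X = _design(gains, losses)
    single_class = len(np.unique(y)) < 2
    if n < min_trials or single_class:
        beta, cov, ok = _ridge_logistic(X, y, prior_sd)
        return LogisticFit(*beta, cov=cov, converged=ok,
                           flag="degenerate", n_obs=n)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=100)
        beta = res.params
        cov = np.asarray(res.cov_params())
        diverged = (not np.all(np.isfinite(beta))) or np.max(np.abs(beta)) > 1e2 \
            or not np.all(np.isfinite(cov))
    except Exception:
        diverged = True
    if diverged:
        beta, cov, ok = _ridge_logistic(X, y, prior_sd)
        return LogisticFit(*beta, cov=cov, converged=ok, flag="ridge", n_obs=n)
    return LogisticFit(float(beta[0]), float(beta[1]), float(beta[2]),
                       cov=cov, converged=True, flag=None, n_obs=n)


def loss_aversion_index(fit: LogisticFit) -> float:
    """lambda = ln(wL / wG); NaN when either sensitivity is non-positive.

    The log-ratio is invariant to multiplying all coefficients by a
    positive constant, so it is not confounded by behavioral temperature.
    """
    if fit.wG > 0 and fit.wL > 0:
        return float(np.log(fit.wL / fit.wG))
    return float("nan")


def predict_probabilities(fit: LogisticFit, data: ChoiceDataset) -> np.ndarray:
    gains, losses, _, _, _ = data.arrays()
    eta = _design(gains, losses) @ np.array([fit.w0, fit.wG, fit.wL])
    return 1.0 / (1.0 + np.exp(-eta))


def balanced_accuracy(predictions, observed) -> float:
    """Mean of sensitivity and specificity, in percent.

    ``predictions`` may be probabilities (thresholded at 0.5) or binary.
    With a single observed class, returns accuracy on the present class
    (same value, one term).  Missing observations are dropped.
    """
    p = np.asarray(predictions, float)
    y = np.asarray(observed, float)
    keep = np.isfinite(y) & np.isfinite(p)
    p, y = p[keep], y[keep]
    pred = (p >= 0.5).astype(float)
    terms = []
    for cls, name in ((1.0, "sens"), (0.0, "spec")):
        mask = y == cls
        if mask.any():
            terms.append(np.mean(pred[mask] == cls))
    return float(100.0 * np.mean(terms))


def sliding_window_loss_aversion(data: ChoiceDataset, window: int = 16) -> pd.DataFrame:
    """Loss-aversion dynamics over non-overlapping windows of trials.

    Each chunk of ``window`` consecutive trials gets its own logistic fit;
    a trailing remainder is dropped with a warning.  Returns a DataFrame
    with one row per window (window index, w0, wG, wL, lambda, flag).
    """
    if window < 8:
        raise ValueError("windows of fewer than 8 trials are unidentifiable")
    n = data.n_trials
    n_windows = n // window
    if n % window:
        warnings.warn(f"dropping trailing {n % window} trials")
    rows = []
    for wdx in range(n_windows):
        idx = np.arange(wdx * window, (wdx + 1) * window)
        fit = fit_choice_logistic(data.subset(idx), min_trials=4)
        rows.append({
            "window": wdx, "w0": fit.w0, "wG": fit.wG, "wL": fit.wL,
            "loss_aversion": fit.loss_aversion, "flag": fit.flag,
        })
    return pd.DataFrame(rows)


def ev_decile_curve(data: ChoiceDataset, n_bins: int = 10):
    """Acceptance rate per within-subject EV quantile bin.

    Returns ``(bin_centers, rates, merged_flag)``; heavy EV ties can
    produce fewer than ``n_bins`` distinct quantile edges, in which case
    bins are merged and flagged.
    """
    gains, losses, evs, _, accept = data.arrays()
    keep = np.isfinite(accept)
    evs, accept = evs[keep], accept[keep]
    if evs.size < n_bins:
        raise ValueError("need at least as many trials as bins")
    edges = np.quantile(evs, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    merged = len(edges) < n_bins + 1
    idx = np.clip(np.digitize(evs, edges[1:-1]), 0, len(edges) - 2)
    centers = np.array([evs[idx == b].mean() for b in range(len(edges) - 1)])
    rates = np.array([accept[idx == b].mean() for b in range(len(edges) - 1)])
    return centers, rates, merged


def group_f_test(values_group1, values_group2):
    """One-way pooled-variance F test for a two-group mean difference.

    Equivalent to the square of the pooled two-sample t statistic, with
    dof = n1 + n2 - 2.  Returns (F, dof, p).
    """
    a = np.asarray(values_group1, float)
    b = np.asarray(values_group2, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    t, _ = stats.ttest_ind(a, b, equal_var=True)
    dof = a.size + b.size - 2
    if not np.isfinite(t):
        return float("nan"), dof, float("nan")
    F = float(t ** 2)
    p = float(stats.f.sf(F, 1, dof))
    return F, dof, p


def common_ev_mask(trials: Sequence[GambleTrial], design_a, design_b) -> np.ndarray:
    """Mark trials whose EV lies in the intersection of two designs' EV ranges.

    The EV ranges come from the design specifications (objects exposing
    ``gain_levels`` / ``loss_levels``, e.g.
    :class:`evsynth.synth.GroupDesignSpec`), not from observed data.  For
    the two study designs the intersection is [-5, 7.5] dollars.
    """

    def ev_range(spec):
        g = np.asarray(spec.gain_levels, float)
        l = np.asarray(spec.loss_levels, float)
        return (g.min() - l.max()) / 2.0, (g.max() - l.min()) / 2.0

    lo_a, hi_a = ev_range(design_a)
    lo_b, hi_b = ev_range(design_b)
    lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
    if lo > hi:
        raise ValueError("the two designs' EV ranges do not intersect")
    _, _, evs, _ = trials_to_arrays(trials)
    return (evs >= lo) & (evs <= hi)
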