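"""MAP fitting of the value-synthesis network to choice series.

Plastic and static network variants are fitted to each subject's
sequential accept/reject decisions by maximizing the Bernoulli log
likelihood of the choices (with p(accept) = sigmoid(b + V_t), V_t from
the sequential forward/plasticity pass) plus Gaussian log priors.

Parameterization (an identifiability-driven choice): the initial
connectivity C_0 is a fixed random draw from a subject-specific seed and
is NOT fitted — free per-attribute input gains and the free readout
vector w provide the flexible value landscape.  The readout is
constrained to the sum-zero subspace (parameterized in an orthonormal
basis of it): a uniform readout component is redundant with the decision
bias on stationary activity, and under plasticity it would convert the
recentering of unit activities into a spurious value drift, confounding
the adaptation parameters.  Free parameters are

    b                 decision bias                     prior N(0, 2^2)
    w coords (n_z-1)  sum-zero readout coordinates      prior N(0, 2^2) each
    log input gains   one per attribute                 prior N(0, 0.5^2)
    logit alpha/beta  plasticity (plastic variant only) prior N(logit 0.1, 2^2)

The static variant pins alpha = beta = 0 exactly and removes the last
two parameters; it is nested in the plastic variant (pinning alpha to 0
reproduces the static likelihood exactly).

Optimization is deterministic seeded multi-start L-BFGS with numerical
gradients; only MAP point estimates and the negative log joint are
reported (no posterior approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .core import MONEY_NORM, NetworkParams, make_network
from .engine import run_sequence_raw
from .behavior import ChoiceDataset, balanced_accuracy, fit_choice_logistic
from .simulation import train_readout_to_ev

__all__ = [
    "FitConfig",
    "FittedModel",
    "fit_ann_to_choices",
    "postdict",
    "counterfactual_predict",
    "out_of_sample_error",
    "parameter_recovery",
    "fit_cohort",
    "counterfactual_group_rates",
]


@dataclass(frozen=True)
class FitConfig:
    """Fixed structure, priors and optimizer settings for one subject fit."""

    n_x: int = 8
    n_z: int = 16
    c_scale: float = 3.0
    money_norm: float = MONEY_NORM
    subject_seed: int = 0          # seeds the frozen C_0 draw
    n_starts: int = 8
    max_iter: int = 300
    tol: float = 1e-8
    seed: int = 0                  # seeds the multi-start initializations
    prior_sd_b: float = 2.0
    prior_sd_w: float = 2.0
    prior_loggain_sd: float = 0.5
    prior_logit_mean: float = float(logit(0.1))
    prior_logit_sd: float = 2.0


@dataclass
class FittedModel:
    """MAP estimate of one network variant for one subject."""

    variant: str                   # "plastic" | "static"
    subject_id: str
    config: FitConfig
    bias: float
    w: np.ndarray
    input_gains: np.ndarray        # multiplicative, per attribute
    alpha: float
    beta: float
    nll: float                     # choice negative log likelihood at MAP
    neg_log_joint: float
    p_post: np.ndarray             # per-trial postdicted p(accept)
    converged: bool
    n_starts_converged: int = 0

    @property
    def x_vector(self) -> np.ndarray:
        basis = _sum_zero_basis(len(self.w))
        base = [self.bias, *(basis.T @ self.w), *np.log(self.input_gains)]
        if self.variant == "plastic":
            base += [float(logit(self.alpha)), float(logit(self.beta))]
        return np.array(base)


def _base_network(config: FitConfig) -> NetworkParams:
    return make_network(n_x=config.n_x, n_z=config.n_z,
                        seed=config.subject_seed, c_scale=config.c_scale)


def _sum_zero_basis(n_z: int) -> np.ndarray:
    """Orthonormal basis (n_z x n_z-1) of the sum-zero readout subspace."""
    return np.linalg.svd(np.ones((1, n_z)))[2][1:].T


def _unpack(x: np.ndarray, config: FitConfig, variant: str, basis: np.ndarray):
    n_z = config.n_z
    b = x[0]
    w = basis @ x[1:n_z]
    gains = np.exp(x[n_z:n_z + 2])
    if variant == "plastic":
        alpha = float(expit(x[n_z + 2]))
        beta = float(expit(x[n_z + 3]))
    else:
        alpha = beta = 0.0
    return b, w, gains, alpha, beta


def _n_free(config: FitConfig, variant: str) -> int:
    return 2 + config.n_z + (2 if variant == "plastic" else 0)


def _sequence_p(x, config, variant, net, g_norm, l_norm):
    b, w, gains, alpha, beta = _unpack(x, config, variant, net._basis)
    P, _, _, _, _, _, _ = run_sequence_raw(
        net._mu_x, net._sig_x, net._mu_z, net._sig_z, net._C,
        np.ascontiguousarray(w), float(b), alpha, beta,
        gains[0] * g_norm, gains[1] * l_norm,
    )
    return P


class _FrozenNet:
    """Contiguous flattened copies of the fixed network arrays."""

    def __init__(self, params: NetworkParams):
        self._mu_x = np.ascontiguousarray(params.attr_mu.ravel())
        self._sig_x = np.ascontiguousarray(params.attr_sigma.ravel())
        self._mu_z = np.ascontiguousarray(params.z_mu)
        self._sig_z = np.ascontiguousarray(params.z_sigma)
        self._C = np.ascontiguousarray(params.C)
        self._basis = _sum_zero_basis(params.n_z)


def _neg_log_joint(x, config, variant, net, g_norm, l_norm, y, mask):
    P = _sequence_p(x, config, variant, net, g_norm, l_norm)
    p = np.clip(P[mask], 1e-12, 1.0 - 1e-12)
    yy = y[mask]
    nll = -float(np.sum(yy * np.log(p) + (1.0 - yy) * np.log(1.0 - p)))
    n_z = config.n_z
    pen = 0.5 * (x[0] / config.prior_sd_b) ** 2
    pen += 0.5 * float(np.sum((x[1:n_z] / config.prior_sd_w) ** 2))
    pen += 0.5 * float(np.sum((x[n_z:n_z + 2] / config.prior_loggain_sd) ** 2))
    if variant == "plastic":
        d = (x[n_z + 2:n_z + 4] - config.prior_logit_mean) / config.prior_logit_sd
        pen += 0.5 * float(np.sum(d ** 2))
    return nll + pen


def _warm_start(config, variant, net_params, basis, g_norm, l_norm, y, mask):
    """Initialize near a linear-value solution: sum-zero readout trained
    to EV, temperature from a quick logistic fit of choices on EV."""
    w_ev, _, _ = train_readout_to_ev(net_params, g_norm, l_norm, sum_zero=True)
    ev = (g_norm - l_norm) / 2.0
    A = np.column_stack([np.ones(mask.sum()), ev[mask]])
    # crude logistic on EV via a few IRLS steps
    beta = np.zeros(2)
    yy = y[mask]
    for _ in range(25):
        p = expit(A @ beta)
        Wt = np.clip(p * (1 - p), 1e-6, None)
        H = (A * Wt[:, None]).T @ A + 1e-6 * np.eye(2)
        beta = beta + np.linalg.solve(H, A.T @ (yy - p))
        beta = np.clip(beta, -50, 50)
    x0 = np.zeros(_n_free(config, variant))
    x0[0] = beta[0]
    x0[1:config.n_z] = np.clip(beta[1], -40, 40) * (basis.T @ w_ev)
    if variant == "plastic":
        x0[config.n_z + 2:config.n_z + 4] = config.prior_logit_mean
    return x0


def fit_ann_to_choices(data: ChoiceDataset, config: FitConfig,
                       variant: str = "plastic") -> FittedModel:
    """MAP fit of one network variant to one subject's choice series.

    Deterministic given ``config.seed``: multi-start initializations are
    seeded, each start runs L-BFGS on the negative log joint, and the
    best optimum is kept.  Non-convergence of every start returns the
    best point found, flagged via ``converged``.
    """
    if variant not in ("plastic", "static"):
        raise ValueError("variant must be 'plastic' or 'static'")
    gains, losses, _, _, accept = data.arrays()
    mask = np.isfinite(accept)
    if mask.sum() < 64:
        raise ValueError("need at least 64 non-missing trials")
    y = np.where(mask, accept, 0.0)
    g_norm = np.ascontiguousarray(gains / config.money_norm)
    l_norm = np.ascontiguousarray(losses / config.money_norm)
    net_params = _base_network(config)
    net = _FrozenNet(net_params)
    obj = lambda x: _neg_log_joint(x, config, variant, net, g_norm, l_norm, y, mask)

    rng = np.random.default_rng(config.seed)
    x_warm = _warm_start(config, variant, net_params, net._basis,
                         g_norm, l_norm, y, mask)
    starts = [x_warm]
    for _ in range(config.n_starts - 1):
        x = x_warm.copy()
        x[0] += rng.normal(0, 0.5)
        x[1:config.n_z] += rng.normal(0, 1.0, config.n_z - 1)
        x[config.n_z:config.n_z + 2] += rng.normal(0, 0.3, 2)
        if variant == "plastic":
            x[config.n_z + 2:config.n_z + 4] += rng.normal(0, 1.0, 2)
        starts.append(x)

    best = None
    n_ok = 0
    for x0 in starts:
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B",
            options={"maxiter": config.max_iter, "ftol": config.tol},
        )
        n_ok += int(res.success)
        if best is None or res.fun < best.fun:
            best = res
    b, w, in_gains, alpha, beta = _unpack(best.x, config, variant, net._basis)
    P = _sequence_p(best.x, config, variant, net, g_norm, l_norm)
    p = np.clip(P[mask], 1e-12, 1 - 1e-12)
    nll = -float(np.sum(y[mask] * np.log(p) + (1 - y[mask]) * np.log(1 - p)))
    return FittedModel(
        variant=variant, subject_id=data.subject_id, config=config,
        bias=float(b), w=np.asarray(w), input_gains=np.asarray(in_gains),
        alpha=alpha, beta=beta, nll=nll, neg_log_joint=float(best.fun),
        p_post=P, converged=n_ok > 0, n_starts_converged=n_ok,
    )


def postdict(model: FittedModel, data: ChoiceDataset) -> dict:
    """Model agreement with its own fitting data.

    Returns per-trial p(accept), balanced accuracy (percent) and variance
    explained, defined as 100 * corr(p, choice)^2 over non-missing trials.
    """
    _, _, _, _, accept = data.arrays()
    mask = np.isfinite(accept)
    p = model.p_post
    ba = balanced_accuracy(p[mask], accept[mask])
    if np.std(p[mask]) < 1e-12 or np.std(accept[mask]) < 1e-12:
        ve = float("nan")
    else:
        ve = float(100.0 * np.corrcoef(p[mask], accept[mask])[0, 1] ** 2)
    return {"p": p, "balanced_accuracy": ba, "variance_explained": ve}


def counterfactual_predict(model: FittedModel, trials) -> np.ndarray:
    """Out-of-sample predictions on another context's trial sequence.

    Resets the plasticity state to its fitted initial condition and runs
    the fitted model forward on the other design; no parameter
    re-adjustment.  Returns per-trial p(accept) and, as an attribute of
    the fit, leaves the model unchanged.
    """
    from .core import trials_to_arrays

    gains, losses, _, _ = trials_to_arrays(trials)
    g_norm = gains / model.config.money_norm
    l_norm = losses / model.config.money_norm
    if np.max(model.input_gains[0] * g_norm) > 50 or \
            np.max(model.input_gains[1] * l_norm) > 50:
        raise ValueError("design outside the canonical input domain")
    net = _FrozenNet(_base_network(model.config))
    alpha = model.alpha if model.variant == "plastic" else 0.0
    beta = model.beta if model.variant == "plastic" else 0.0
    P, _, _, _, _, _, _ = run_sequence_raw(
        net._mu_x, net._sig_x, net._mu_z, net._sig_z, net._C,
        np.ascontiguousarray(model.w), model.bias, alpha, beta,
        np.ascontiguousarray(model.input_gains[0] * g_norm),
        np.ascontiguousarray(model.input_gains[1] * l_norm),
    )
    return P


def out_of_sample_error(predictions, observed) -> float:
    """Mean absolute prediction error |p - choice| over non-missing trials."""
    p = np.asarray(predictions, float)
    y = np.asarray(observed, float)
    if p.shape != y.shape:
        raise ValueError("predictions and choices must align trial-wise")
    keep = np.isfinite(y)
    return float(np.mean(np.abs(p[keep] - y[keep])))


# ---------------------------------------------------------------------
# cohort-level harnesses
# ---------------------------------------------------------------------

def fit_cohort(cohort, config: FitConfig, variant: str = "plastic",
               verbose: bool = False) -> dict:
    """Fit every subject in a synthetic cohort; subject-specific C_0 seeds
    are derived from the subject index (never from the generating agent)."""
    fits = {}
    for i, rec in enumerate(cohort):
        cfg = replace(config, subject_seed=config.subject_seed + 101 * i + 13,
                      seed=config.seed + i)
        fits[rec.subject_id] = fit_ann_to_choices(rec.dataset, cfg, variant)
        if verbose:
            m = fits[rec.subject_id]
            print(f"  {rec.subject_id} [{variant}] nll={m.nll:.1f} "
                  f"alpha={m.alpha:.3f} beta={m.beta:.3f}")
    return fits


def parameter_recovery(cohort, config: FitConfig, variant: str = "plastic") -> pd.DataFrame:
    """Fit a ground-truth cohort and tabulate truth vs estimate per subject."""
    fits = fit_cohort(cohort, config, variant)
    rows = []
    for rec in cohort:
        m = fits[rec.subject_id]
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group,
            "alpha_true": rec.truth.get("alpha", np.nan),
            "beta_true": rec.truth.get("beta", np.nan),
            "bias_true": rec.truth.get("bias", np.nan),
            "alpha_hat": m.alpha, "beta_hat": m.beta, "bias_hat": m.bias,
            "nll": m.nll, "converged": m.converged,
        })
    return pd.DataFrame(rows)


def counterfactual_group_rates(fits: dict, cohort, common_only: bool = True) -> dict:
    """Cross-context out-of-sample gambling-rate comparison.

    Each fitted model predicts the trial sequence of a paired subject
    from the *other* group; predicted acceptance rates are averaged
    within the EV range common to both designs.  Returns the predicted
    rates per context and the group difference (wide-context minus
    narrow-context predictions) in percentage points: positive means the
    models wrongly extrapolate higher gambling in the wide context.
    """
    from .behavior import common_ev_mask
    from .synth import GroupDesignSpec

    narrow = [r for r in cohort if r.group == "narrow"]
    wide = [r for r in cohort if r.group == "wide"]
    spec_n, spec_w = GroupDesignSpec("narrow"), GroupDesignSpec("wide")
    wide_ctx_rates = []     # narrow-fitted models on wide designs
    for i, rec in enumerate(narrow):
        target = wide[i % len(wide)]
        p = counterfactual_predict(fits[rec.subject_id], target.design)
        mask = common_ev_mask(target.design, spec_n, spec_w) if common_only \
            else np.ones(len(p), bool)
        wide_ctx_rates.append(float(np.mean(p[mask])))
    narrow_ctx_rates = []   # wide-fitted models on narrow designs
    for i, rec in enumerate(wide):
        target = narrow[i % len(narrow)]
        p = counterfactual_predict(fits[rec.subject_id], target.design)
        mask = common_ev_mask(target.design, spec_n, spec_w) if common_only \
            else np.ones(len(p), bool)
        narrow_ctx_rates.append(float(np.mean(p[mask])))
    diff = 100.0 * (np.mean(wide_ctx_rates) - np.mean(narrow_ctx_rates))
    return {
        "wide_context_rates": np.array(wide_ctx_rates),
        "narrow_context_rates": np.array(narrow_ctx_rates),
        "group_difference_pct": float(diff),
    }
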