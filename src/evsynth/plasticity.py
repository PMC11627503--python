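"""Self-organized anti-Hebbian plasticity for efficient value synthesis.

Bounded units lose information about value whenever their inputs land in
the saturated tails of the activation function.  At the small-noise limit
the information loss of the integration layer decomposes into (minus) the
entropy of the integration inputs v and (minus) the mean log-steepness of
the activation functions.  Descending the local part of its gradient with
respect to the connectivity C, and replacing the expectation by an
exponentially weighted moving average over trials, yields the update

    dC_t(i,j,k) = alpha (1 - beta) dC_{t-1}(i,j,k)
                  + alpha beta (1 / sigma_z(k)) (1 - 2 z_t(k)) x_t(i,j)

which is local (only the connected pair's outputs enter), self-organized
(no teaching signal) and anti-Hebbian (a connection weakens when its units
co-activate, i.e. x > 0 and z > 1/2).  Setting alpha = 0 or beta = 0
disables adaptation exactly ("static" value synthesis).

Note on the slope factor: the innovation *divides* by sigma_z(k).  This
follows from the derivative chain for the logistic parameterization used
here (f' = f(1-f)/sigma); a multiplicative placement of sigma_z sometimes
seen in shorthand write-ups of this rule is a typographic variant that
coincides with ours at sigma_z = 1, the default.

The non-local entropy-gradient correction term (a whitening-like matrix
factor coupling all connections) is biologically implausible and small in
practice; it is not part of the default rule but can be computed for
diagnostics via :func:`nonlocal_correction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    GambleTrial,
    NetworkParams,
    TrialActivity,
    forward_batch,
    forward_trial,
    trials_to_arrays,
    _sigmoid,
)

__all__ = [
    "PlasticityParams",
    "PlasticityState",
    "InfoLossEstimate",
    "infomax_innovation",
    "plasticity_step",
    "adapt_sequence",
    "AdaptResult",
    "information_loss",
    "nonlocal_correction",
    "attribute_adaptation_step",
    "attribute_adapt_sequence",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Step magnitude ``alpha`` >= 0 and rate ``beta`` in [0, 1].

    ``alpha`` scales the overall magnitude of connectivity changes;
    ``beta`` sets the exponential forgetting of the moving average, hence
    the temporal scale of adaptation.  Either parameter at zero yields
    static (non-adaptive) value synthesis.
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")

    @property
    def is_static(self) -> bool:
        return self.alpha == 0.0 or self.beta == 0.0


@dataclass
class PlasticityState:
    """Carry-over state of the plasticity recursion (dC at trial t-1)."""

    delta_C_prev: np.ndarray
    trial_counter: int = 0
    moving_avg: Optional[np.ndarray] = None  # optional diagnostic E^t trace

    @classmethod
    def initial(cls, params: NetworkParams) -> "PlasticityState":
        return cls(delta_C_prev=np.zeros_like(params.C))


@dataclass(frozen=True)
class InfoLossEstimate:
    """Information loss of the integration layer, up to additive constants.

    ``info_loss = -entropy_term - steepness_term`` where ``entropy_term``
    is the Gaussian approximation ln det(C S C^T) / 2 of the entropy of v
    (S the sample covariance of attribute outputs) and ``steepness_term``
    is the sample mean of sum_k ln(z_k (1 - z_k) / sigma_z(k)).
    """

    entropy_term: float
    steepness_term: float
    S: np.ndarray
    ridged: bool = False

    @property
    def info_loss(self) -> float:
        return -self.entropy_term - self.steepness_term


def infomax_innovation(activity: TrialActivity, z_sigma) -> np.ndarray:
    """Per-trial gradient of sum_k ln|df_z/dv(k)| with respect to C.

    Returns g with g[ij, k] = (1 / sigma_z(k)) (1 - 2 z(k)) x(i, j),
    shape (n_attr * n_x, n_z).
    """
    z_sigma = np.asarray(z_sigma, dtype=float)
    return np.outer(activity.x.ravel(), (1.0 - 2.0 * activity.z) / z_sigma)


def plasticity_step(
    C: np.ndarray,
    state: PlasticityState,
    innovation: np.ndarray,
    params: PlasticityParams,
    track_moving_avg: bool = False,
):
    """One step of the plasticity recursion.

    Computes ``dC_t = alpha (1-beta) dC_{t-1} + alpha beta g`` and returns
    ``(dC_t, C + dC_t, new_state)``.  Inputs are not mutated.
    """
    if innovation.shape != C.shape:
        raise ValueError("innovation shape must match connectivity shape")
    dC = params.alpha * (1.0 - params.beta) * state.delta_C_prev \
        + params.alpha * params.beta * innovation
    moving_avg = None
    if track_moving_avg:
        prev = state.moving_avg if state.moving_avg is not None else np.zeros_like(C)
        moving_avg = (1.0 - params.beta) * prev + params.beta * innovation
    new_state = PlasticityState(
        delta_C_prev=dC,
        trial_counter=state.trial_counter + 1,
        moving_avg=moving_avg,
    )
    return dC, C + dC, new_state


@dataclass
class AdaptResult:
    """Full trajectory of an adaptation run (trial-major arrays)."""

    gains: np.ndarray
    losses: np.ndarray
    X: np.ndarray        # (n_t, n_attr*n_x)
    Vin: np.ndarray      # (n_t, n_z) integration inputs at presentation time
    Z: np.ndarray        # (n_t, n_z)
    V: np.ndarray        # (n_t,)
    C_traj: Optional[np.ndarray]  # (n_t + 1, n_ux, n_z) incl. C_0, or None
    dC_norms: np.ndarray  # (n_t,) Frobenius norm of each dC_t
    params_final: NetworkParams

    def to_frame(self):
        """Tidy long-format table (trial, unit, quantity, value) of z and v."""
        import pandas as pd

        n_t, n_z = self.Z.shape
        trial = np.repeat(np.arange(1, n_t + 1), n_z)
        unit = np.tile(np.arange(n_z), n_t)
        return pd.concat(
            [
                pd.DataFrame({"trial": trial, "unit": unit,
                              "quantity": "z", "value": self.Z.ravel()}),
                pd.DataFrame({"trial": trial, "unit": unit,
                              "quantity": "v", "value": self.Vin.ravel()}),
            ],
            ignore_index=True,
        )


def adapt_sequence(
    params: NetworkParams,
    plasticity: PlasticityParams,
    trials: Sequence[GambleTrial],
    record_C: bool = False,
) -> AdaptResult:
    """Sequentially apply forward passes and plasticity steps over trials.

    Reference (pure-numpy) implementation; a JIT-compiled equivalent used
    by the Monte-Carlo harnesses lives in :mod:`evsynth.engine` and is
    cross-checked against this one in the test suite.  Deterministic given
    its inputs.  The input ``params`` object is not mutated.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    gains, losses, _, _ = trials_to_arrays(trials)
    p = params.copy()
    state = PlasticityState.initial(p)
    n_t = len(trials)
    n_ux, n_z = p.C.shape
    X = np.empty((n_t, n_ux))
    Vin = np.empty((n_t, n_z))
    Z = np.empty((n_t, n_z))
    V = np.empty(n_t)
    dC_norms = np.empty(n_t)
    C_traj = np.empty((n_t + 1, n_ux, n_z)) if record_C else None
    if record_C:
        C_traj[0] = p.C
    for t in range(n_t):
        act = forward_trial(p, (gains[t], losses[t]))
        X[t] = act.x.ravel()
        Vin[t] = act.v
        Z[t] = act.z
        V[t] = act.V
        g = infomax_innovation(act, p.z_sigma)
        dC, C_new, state = plasticity_step(p.C, state, g, plasticity)
        dC_norms[t] = np.linalg.norm(dC)
        p.C = C_new
        if record_C:
            C_traj[t + 1] = C_new
    return AdaptResult(
        gains=gains, losses=losses, X=X, Vin=Vin, Z=Z, V=V,
        C_traj=C_traj, dC_norms=dC_norms, params_final=p,
    )


def information_loss(
    X_samples: np.ndarray,
    C: np.ndarray,
    z_mu,
    z_sigma,
    ridge_scale: float = 1e-8,
) -> InfoLossEstimate:
    """Estimate the information loss of the integration layer from samples.

    Parameters
    ----------
    X_samples
        Attribute-layer outputs, shape (n_samples, n_attr * n_x).
    C, z_mu, z_sigma
        Connectivity and integration-unit activation parameters.
    ridge_scale
        When C S C^T is near-singular, ``ridge_scale * trace / dim`` is
        added to its diagonal before the log-determinant and the estimate
        is flagged ``ridged``.
    """
    X_samples = np.asarray(X_samples, dtype=float)
    if X_samples.ndim != 2 or X_samples.shape[0] < 2:
        raise ValueError("need at least 2 samples of attribute outputs")
    S = np.cov(X_samples, rowvar=False)
    M = C.T @ S @ C
    n_z = M.shape[0]
    sign, logdet = np.linalg.slogdet(M)
    ridged = False
    if sign <= 0 or not np.isfinite(logdet):
        M = M + np.eye(n_z) * (ridge_scale * np.trace(M) / n_z)
        sign, logdet = np.linalg.slogdet(M)
        ridged = True
    entropy_term = 0.5 * logdet
    Vin = X_samples @ C
    Z = _sigmoid(Vin, np.asarray(z_mu, float), np.asarray(z_sigma, float))
    steepness = np.log(Z * (1.0 - Z) / np.asarray(z_sigma, float))
    steepness_term = float(np.mean(np.sum(steepness, axis=1)))
    return InfoLossEstimate(
        entropy_term=float(entropy_term),
        steepness_term=steepness_term,
        S=S,
        ridged=ridged,
    )


def nonlocal_correction(activity: TrialActivity, ridge: float = 1e-10) -> np.ndarray:
    """Diagnostic: the dropped non-local entropy-gradient term.

    Computes [ (v v^T)^{-1} v x^T ]^T for one trial (pseudo-inverted, since
    a single-trial outer product is rank one).  Not used by the default
    rule; exposed so its magnitude can be compared with the local term.
    """
    v = activity.v[:, None]
    x = activity.x.ravel()[None, :]
    M = v @ v.T
    M = M + ridge * np.eye(M.shape[0])
    return (np.linalg.pinv(M) @ v @ x).T


# ---------------------------------------------------------------------
# alternative scenario: efficient coding at the attribute layer
# ---------------------------------------------------------------------

def attribute_adaptation_step(
    attr_mu: np.ndarray,
    attr_sigma: np.ndarray,
    u,
    rate: float,
    min_sigma: float = 1e-3,
):
    """One infomax step on attribute-unit thresholds and slopes.

    Gradient ascent on ln|df_x/du| for each attribute unit (connectivity
    untouched), derived from the same information-loss principle applied
    at the attribute layer instead of the integration layer:

        d mu        = rate * (2 x - 1) / sigma
        d ln sigma  = rate * ((mu - u)(1 - 2 x) / sigma - 1)

    Slopes are floored at ``min_sigma``.  Returns updated (mu, sigma)
    arrays (inputs not mutated).
    """
    if not rate > 0:
        raise ValueError("rate must be strictly positive")
    u = np.asarray(u, dtype=float)[:, None]
    x = _sigmoid(u, attr_mu, attr_sigma)
    new_mu = attr_mu + rate * (2.0 * x - 1.0) / attr_sigma
    dlnsig = rate * ((attr_mu - u) * (1.0 - 2.0 * x) / attr_sigma - 1.0)
    new_sigma = np.maximum(attr_sigma * np.exp(dlnsig), min_sigma)
    return new_mu, new_sigma


def attribute_adapt_sequence(
    params: NetworkParams,
    trials: Sequence[GambleTrial],
    rate: float = 0.01,
    min_sigma: float = 1e-3,
) -> AdaptResult:
    """Run the attribute-layer adaptation scenario over a trial sequence.

    Connectivity C stays fixed; attribute thresholds/slopes adapt.  The
    returned trajectory has the same layout as :func:`adapt_sequence`
    (with ``C_traj`` None and zero ``dC_norms``).
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    gains, losses, _, _ = trials_to_arrays(trials)
    p = params.copy()
    n_t = len(trials)
    n_ux, n_z = p.C.shape
    X = np.empty((n_t, n_ux))
    Vin = np.empty((n_t, n_z))
    Z = np.empty((n_t, n_z))
    V = np.empty(n_t)
    for t in range(n_t):
        act = forward_trial(p, (gains[t], losses[t]))
        X[t] = act.x.ravel()
        Vin[t] = act.v
        Z[t] = act.z
        V[t] = act.V
        p.attr_mu, p.attr_sigma = attribute_adaptation_step(
            p.attr_mu, p.attr_sigma, (gains[t], losses[t]), rate, min_sigma
        )
    return AdaptResult(
        gains=gains, losses=losses, X=X, Vin=Vin, Z=Z, V=V,
        C_traj=None, dC_norms=np.zeros(n_t), params_final=p,
    )
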