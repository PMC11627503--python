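"""Two-layer bounded-response network for gamble value construction.

The network maps a 50/50 gamble's prospective gain G and loss L (both
entered as positive magnitudes) onto a scalar value signal V.  Each
attribute feeds a dedicated sublayer of sigmoidal units whose outputs are
mixed, through a connectivity matrix C, into a layer of integration units;
value is read out from the integration layer with a linear population code:

    x(i,j) = f(u(i); mu_x(i,j), sigma_x(i,j))      attribute sublayers
    v(k)   = sum_ij C(i,j,k) x(i,j)                integration inputs
    z(k)   = f(v(k); mu_z(k), sigma_z(k))          integration outputs
    V      = sum_k w(k) z(k)                       population readout

with f the logistic sigmoid f(u) = 1 / (1 + exp((mu - u) / sigma)).
Bounded (saturating) activation is the central biological constraint: a
unit cannot discriminate inputs that land in its saturated tails, which is
what creates the need for the range adaptation implemented in
:mod:`evsynth.plasticity`.

Money is mapped affinely onto a canonical [0, 1] domain by dividing by
``MONEY_NORM`` (default $40, the largest amount in either study design).
All network-level functions operate on the canonical domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MONEY_NORM",
    "GambleTrial",
    "ActivationParams",
    "NetworkParams",
    "TrialActivity",
    "NoiseParams",
    "sigmoid_response",
    "forward_trial",
    "forward_batch",
    "choice_probability",
    "add_response_noise",
    "receptive_field_map",
    "make_network",
    "normalize_money",
    "trials_to_arrays",
]

#: Canonical money normalization constant, in dollars.
MONEY_NORM = 40.0


def normalize_money(amount):
    """Affinely map dollar amounts onto the canonical [0, 1] input domain."""
    return np.asarray(amount, dtype=float) / MONEY_NORM


@dataclass(frozen=True)
class GambleTrial:
    """One 50/50 gamble: win ``gain`` or lose ``loss`` with equal odds.

    Both amounts are stored as positive magnitudes.  The expected value
    is ``ev = (gain - loss) / 2`` and is always recomputed, never stored.
    """

    gain: float
    loss: float
    trial_index: int = 1
    session: int = 1

    def __post_init__(self):
        if self.gain < 0 or self.loss < 0:
            raise ValueError("gain and loss must be non-negative magnitudes")

    @property
    def ev(self) -> float:
        return (self.gain - self.loss) / 2.0


def trials_to_arrays(trials: Sequence[GambleTrial]):
    """Return (gains, losses, evs, sessions) arrays for a trial sequence."""
    gains = np.array([t.gain for t in trials], dtype=float)
    losses = np.array([t.loss for t in trials], dtype=float)
    sessions = np.array([t.session for t in trials], dtype=int)
    return gains, losses, (gains - losses) / 2.0, sessions


@dataclass(frozen=True)
class ActivationParams:
    """Threshold ``mu`` and slope ``sigma`` (> 0) of one sigmoidal unit."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be strictly positive, got {self.sigma}")


@dataclass
class NetworkParams:
    """Full parameter set of the two-layer value-synthesis network.

    Attributes
    ----------
    attr_mu, attr_sigma
        Thresholds and slopes of attribute units, shape (n_attr, n_x).
        Attribute 0 receives the gain, attribute 1 the loss magnitude.
    z_mu, z_sigma
        Thresholds and slopes of the n_z integration units.
    C
        Connectivity, shape (n_attr * n_x, n_z); row order is attribute-major
        (all gain units first, then all loss units).
    w
        Linear readout weights, length n_z.
    bias
        Decision bias added to V inside :func:`choice_probability` (the
        value readout itself has no intercept).
    """

    attr_mu: np.ndarray
    attr_sigma: np.ndarray
    z_mu: np.ndarray
    z_sigma: np.ndarray
    C: np.ndarray
    w: np.ndarray
    bias: float = 0.0

    def __post_init__(self):
        self.attr_mu = np.asarray(self.attr_mu, dtype=float)
        self.attr_sigma = np.asarray(self.attr_sigma, dtype=float)
        self.z_mu = np.asarray(self.z_mu, dtype=float)
        self.z_sigma = np.asarray(self.z_sigma, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.validate()

    # -- structure ----------------------------------------------------
    @property
    def n_attr(self) -> int:
        return self.attr_mu.shape[0]

    @property
    def n_x(self) -> int:
        return self.attr_mu.shape[1]

    @property
    def n_z(self) -> int:
        return self.z_mu.shape[0]

    def validate(self) -> None:
        if self.attr_mu.shape != self.attr_sigma.shape or self.attr_mu.ndim != 2:
            raise ValueError("attribute parameter arrays must share shape (n_attr, n_x)")
        if self.z_mu.shape != self.z_sigma.shape or self.z_mu.ndim != 1:
            raise ValueError("integration parameter arrays must share shape (n_z,)")
        if np.any(self.attr_sigma <= 0) or np.any(self.z_sigma <= 0):
            raise ValueError("all slope parameters must be strictly positive")
        n_ux = self.n_attr * self.n_x
        if self.C.shape != (n_ux, self.n_z):
            raise ValueError(
                f"C must have shape ({n_ux}, {self.n_z}), got {self.C.shape}"
            )
        if self.w.shape != (self.n_z,):
            raise ValueError(f"w must have shape ({self.n_z},), got {self.w.shape}")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            attr_mu=self.attr_mu.copy(),
            attr_sigma=self.attr_sigma.copy(),
            z_mu=self.z_mu.copy(),
            z_sigma=self.z_sigma.copy(),
            C=self.C.copy(),
            w=self.w.copy(),
            bias=self.bias,
        )

    # -- serialization ------------------------------------------------
    def to_config(self) -> dict:
        return {
            "attr_mu": self.attr_mu.tolist(),
            "attr_sigma": self.attr_sigma.tolist(),
            "z_mu": self.z_mu.tolist(),
            "z_sigma": self.z_sigma.tolist(),
            "C": self.C.tolist(),
            "w": self.w.tolist(),
            "bias": self.bias,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "NetworkParams":
        return cls(**{k: cfg[k] for k in
                      ("attr_mu", "attr_sigma", "z_mu", "z_sigma", "C", "w", "bias")})

    def to_json(self) -> str:
        return json.dumps(self.to_config())

    @classmethod
    def from_json(cls, text: str) -> "NetworkParams":
        return cls.from_config(json.loads(text))


@dataclass(frozen=True)
class TrialActivity:
    """All unit activities produced by one forward pass."""

    x: np.ndarray  # (n_attr, n_x), attribute outputs in (0, 1)
    v: np.ndarray  # (n_z,), integration inputs
    z: np.ndarray  # (n_z,), integration outputs in (0, 1)
    V: float       # readout value


@dataclass(frozen=True)
class NoiseParams:
    """Additive zero-mean Gaussian response noise on the integration layer."""

    sd: float
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


# ---------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------

def _sigmoid(u, mu, sigma):
    return 1.0 / (1.0 + np.exp((mu - u) / sigma))


def sigmoid_response(u: float, params: ActivationParams) -> float:
    """Logistic response 1 / (1 + exp((mu - u) / sigma)) of one unit.

    Strictly increasing in ``u`` and bounded in (0, 1); equals 0.5 at the
    threshold ``u == mu``.
    """
    if not params.sigma > 0:
        raise ValueError("sigma must be strictly positive")
    return float(_sigmoid(u, params.mu, params.sigma))


def forward_trial(params: NetworkParams, trial) -> TrialActivity:
    """Deterministic forward pass for a single gamble.

    ``trial`` may be a :class:`GambleTrial` or a ``(gain, loss)`` pair;
    attributes must already be on the canonical [0, 1] domain.
    """
    if isinstance(trial, GambleTrial):
        u = np.array([trial.gain, trial.loss], dtype=float)
    else:
        u = np.asarray(trial, dtype=float)
    if u.shape != (params.n_attr,):
        raise ValueError(f"expected {params.n_attr} attribute inputs, got {u.shape}")
    x = _sigmoid(u[:, None], params.attr_mu, params.attr_sigma)
    v = params.C.T @ x.ravel()
    z = _sigmoid(v, params.z_mu, params.z_sigma)
    V = float(params.w @ z)
    return TrialActivity(x=x, v=v, z=z, V=V)


def forward_batch(params: NetworkParams, gains, losses):
    """Vectorized static forward pass over many trials.

    Returns ``(X, Vin, Z, V)`` with shapes (n_t, n_attr*n_x), (n_t, n_z),
    (n_t, n_z) and (n_t,).  Connectivity is held fixed (no plasticity).
    """
    gains = np.asarray(gains, dtype=float)
    losses = np.asarray(losses, dtype=float)
    u = np.stack([gains, losses], axis=1)            # (n_t, n_attr)
    X = _sigmoid(u[:, :, None], params.attr_mu[None], params.attr_sigma[None])
    Xf = X.reshape(len(gains), -1)
    Vin = Xf @ params.C
    Z = _sigmoid(Vin, params.z_mu, params.z_sigma)
    V = Z @ params.w
    return Xf, Vin, Z, V


def choice_probability(activity, bias: float = 0.0) -> float:
    """Probability of accepting the gamble: sigmoid(bias + V), unit slope.

    No separate temperature parameter exists; the readout weights absorb
    the behavioral temperature.
    """
    V = activity.V if isinstance(activity, TrialActivity) else float(activity)
    return float(1.0 / (1.0 + np.exp(-(bias + V))))


def add_response_noise(activity: TrialActivity, noise: NoiseParams) -> np.ndarray:
    """Return z + eta with eta i.i.d. N(0, sd^2); reproducible from the seed."""
    rng = np.random.default_rng(noise.seed)
    return activity.z + rng.normal(0.0, noise.sd, size=activity.z.shape)


def receptive_field_map(params: NetworkParams, k: int, gain_grid, loss_grid) -> np.ndarray:
    """Response z(k) of one integration unit over a (gain, loss) grid.

    Returns a matrix of shape (len(gain_grid), len(loss_grid)).
    """
    gain_grid = np.asarray(gain_grid, dtype=float)
    loss_grid = np.asarray(loss_grid, dtype=float)
    if gain_grid.size == 0 or loss_grid.size == 0:
        raise ValueError("receptive field grid must be non-empty")
    G, L = np.meshgrid(gain_grid, loss_grid, indexing="ij")
    _, _, Z, _ = forward_batch(params, G.ravel(), L.ravel())
    return Z[:, k].reshape(G.shape)


# ---------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------

def make_network(
    n_x: int = 8,
    n_z: int = 16,
    seed: int = 0,
    c_scale: float = 3.0,
    bias: float = 0.0,
    n_attr: int = 2,
) -> NetworkParams:
    """Build a network with tiled attribute units and random connectivity.

    Attribute thresholds are evenly spaced over the canonical [0, 1] domain
    with slope equal to half the spacing, so the population tiles the input
    range.  Integration units are homogeneous (mu_z = 0, sigma_z = 1): the
    adapted quantity is the location/scale of their inputs v, set by C.
    Connectivity entries are i.i.d. N(0, (c_scale / sqrt(n_attr*n_x))^2) so
    that initial inputs realistically sample the saturating range.  Readout
    weights start at zero; train them with
    :func:`evsynth.simulation.train_readout_to_ev`.
    """
    rng = np.random.default_rng(seed)
    mu = np.linspace(0.0, 1.0, n_x) if n_x > 1 else np.array([0.5])
    spacing = 1.0 / (n_x - 1) if n_x > 1 else 1.0
    attr_mu = np.tile(mu, (n_attr, 1))
    attr_sigma = np.full((n_attr, n_x), spacing / 2.0)
    n_ux = n_attr * n_x
    C = rng.normal(0.0, c_scale / np.sqrt(n_ux), size=(n_ux, n_z))
    return NetworkParams(
        attr_mu=attr_mu,
        attr_sigma=attr_sigma,
        z_mu=np.zeros(n_z),
        z_sigma=np.ones(n_z),
        C=C,
        w=np.zeros(n_z),
        bias=bias,
    )
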