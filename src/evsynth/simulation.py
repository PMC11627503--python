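"""Monte-Carlo harnesses for range-adaptation experiments.

These reproduce, on the canonical [0, 1] money domain, the simulation
protocols behind the core predictions of efficient value synthesis:

* apparent value range adaptation (EV-binned integration-unit response
  curves across narrow/wide gain and loss ranges),
* the gain/loss-range grid of neural encoding strengths, behavioral
  sensitivities and loss aversion,
* robustness of choice to integration-layer noise (adapted vs static),
* classification of integration units into choice / chosen-value /
  offer-value cells.

A condition is a factorial design of n_levels x n_levels gain/loss
combinations presented once each in random order (the study designs use
16 x 16 = 256).  Each Monte-Carlo run draws a fresh random connectivity,
trains the linear readout to output expected value EV = (G - L)/2 over
the condition's grid, freezes the readout, and lets the connectivity
self-organize over the trial sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GambleTrial, NetworkParams, forward_batch, make_network, trials_to_arrays
from .engine import run_sequence
from .plasticity import PlasticityParams, attribute_adapt_sequence
from . import rsa

__all__ = [
    "RangeCondition",
    "NARROW", "WIDE",
    "make_factorial_design",
    "train_readout_to_ev",
    "run_condition",
    "RunSummary",
    "DEFAULT_PLASTICITY",
    "ev_binned_unit_curves",
    "behavioral_sensitivities",
    "range_grid_sweep",
    "classify_value_cells",
    "noise_robustness_curve",
    "responsive_fraction",
]

#: Canonical narrow / wide range bounds on the unit domain.  All
#: conditions share lower bound 0; "narrow" spans half the unit interval.
NARROW = (0.0, 0.5)
WIDE = (0.0, 1.0)

#: Default plasticity setting for the Monte-Carlo experiments: strong
#: enough that self-organization reaches a steady state well within a
#: 256-trial session, weak enough that adapted units keep responsive
#: variability spanning their output range rather than pinning at 1/2.
DEFAULT_PLASTICITY = PlasticityParams(alpha=0.1, beta=0.1)


@dataclass(frozen=True)
class RangeCondition:
    """A spanned gain/loss domain with its factorial trial design."""

    gain_range: tuple = NARROW
    loss_range: tuple = NARROW
    n_levels: int = 16
    n_trials: int = 256

    def __post_init__(self):
        for lo, hi in (self.gain_range, self.loss_range):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("ranges must satisfy 0 <= lo < hi <= 1")
        if self.n_trials % (self.n_levels ** 2) != 0:
            raise ValueError("n_trials must be a multiple of n_levels^2")

    @property
    def gain_levels(self) -> np.ndarray:
        return np.linspace(*self.gain_range, self.n_levels)

    @property
    def loss_levels(self) -> np.ndarray:
        return np.linspace(*self.loss_range, self.n_levels)

    def grid(self):
        """All (gain, loss) level combinations, gain-major."""
        G, L = np.meshgrid(self.gain_levels, self.loss_levels, indexing="ij")
        return G.ravel(), L.ravel()


def make_factorial_design(condition: RangeCondition, seed: int = 0):
    """Full factorial design, each combination equally often, seeded shuffle."""
    g, l = condition.grid()
    reps = condition.n_trials // (condition.n_levels ** 2)
    g = np.tile(g, reps)
    l = np.tile(l, reps)
    rng = np.random.default_rng(seed)
    order = rng.permutation(condition.n_trials)
    return [
        GambleTrial(gain=float(g[o]), loss=float(l[o]), trial_index=t + 1)
        for t, o in enumerate(order)
    ]


def train_readout_to_ev(params: NetworkParams, gains, losses, sum_zero: bool = False):
    """Least-squares readout weights mapping z-patterns to EV on a grid.

    Returns ``(w, residual_rms, r2)``; minimum-norm solution when the z
    features are degenerate (a rank warning is encoded in r2 rather than
    raised, since random saturated nets routinely have near-duplicate
    units).  With ``sum_zero=True`` the weights are constrained to sum to
    zero, making the readout invariant to uniform activity drift (used by
    the ground-truth choosers, whose value signal would otherwise pick up
    a bias as adaptation recenters all units).  The caller decides whether
    to install ``w`` on the network.
    """
    gains = np.asarray(gains, float)
    losses = np.asarray(losses, float)
    _, _, Z, _ = forward_batch(params, gains, losses)
    ev = (gains - losses) / 2.0
    if sum_zero:
        n_z = Z.shape[1]
        null_basis = np.linalg.svd(np.ones((1, n_z)))[2][1:].T
        a, _, rank, _ = np.linalg.lstsq(Z @ null_basis, ev, rcond=None)
        w = null_basis @ a
    else:
        w, _, rank, _ = np.linalg.lstsq(Z, ev, rcond=None)
    pred = Z @ w
    resid = ev - pred
    rms = float(np.sqrt(np.mean(resid ** 2)))
    denom = float(np.sum((ev - ev.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / denom if denom > 0 else np.nan
    return w, rms, r2


def responsive_fraction(Vin: np.ndarray, z_mu, z_sigma, width: float = 2.0) -> float:
    """Fraction of integration inputs within mu_z +/- width * sigma_z."""
    z_mu = np.asarray(z_mu, float)
    z_sigma = np.asarray(z_sigma, float)
    inside = np.abs(Vin - z_mu) <= width * z_sigma
    return float(np.mean(inside))


@dataclass
class RunSummary:
    """Per-run scalar summaries of one Monte-Carlo adaptation run."""

    responsive_pre: float
    responsive_post: float
    enc_gain: float
    enc_loss: float
    enc_ev: float
    b_gain: float
    b_loss: float
    la_ratio: float
    readout_r2: float
    dc_norm_first: float   # mean |dC_t| over the first 32 trials
    dc_norm_last: float    # ... and the last 32


def _summarize_run(condition, params_pre, params_post, Vin_traj, design_arrays):
    gains, losses = design_arrays
    evs = (gains - losses) / 2.0
    # pre/post responsive fractions on the same design, static evaluation
    _, Vin_pre, _, _ = forward_batch(params_pre, gains, losses)
    _, Vin_post, Z_post, _ = forward_batch(params_post, gains, losses)
    rdm = rsa.compute_rdm(Z_post.T)
    enc = rsa.attribute_encoding_strength(rdm, gains, losses)
    ev_slope, _ = rsa.ev_encoding_strength(rdm, evs)
    b_g, b_l, ratio = behavioral_sensitivities(params_post, condition)
    return {
        "responsive_pre": responsive_fraction(Vin_pre, params_pre.z_mu, params_pre.z_sigma),
        "responsive_post": responsive_fraction(Vin_post, params_post.z_mu, params_post.z_sigma),
        "enc_gain": enc.slope_gain,
        "enc_loss": enc.slope_loss,
        "enc_ev": ev_slope,
        "b_gain": b_g,
        "b_loss": b_l,
        "la_ratio": ratio,
        "Z_post": Z_post,
    }


def run_condition(
    condition: RangeCondition,
    plasticity: PlasticityParams,
    n_runs: int = 1000,
    seed: int = 0,
    n_x: int = 8,
    n_z: int = 16,
    c_scale: float = 3.0,
    keep_arrays: bool = False,
    scenario: str = "value",
):
    """Monte-Carlo over randomized networks adapting to one condition.

    Per run: randomize C, train the readout to EV over the condition grid
    (then freeze it), run the plasticity rule over a freshly shuffled
    factorial trial sequence, and summarize the adapted network.  With
    ``scenario="attribute"`` the alternative attribute-layer adaptation
    rule runs instead of connectivity plasticity.

    Returns ``(summaries, runs)`` where ``summaries`` is a DataFrame of
    :class:`RunSummary` rows and ``runs`` a list of per-run dicts holding
    post-adaptation activities (plus trajectories when ``keep_arrays``).
    """
    rows = []
    runs = []
    for r in range(n_runs):
        run_seed = seed * 100003 + r
        params = make_network(n_x=n_x, n_z=n_z, seed=run_seed, c_scale=c_scale)
        design = make_factorial_design(condition, seed=run_seed + 1)
        gains, losses, evs, _ = trials_to_arrays(design)
        w, _, r2 = train_readout_to_ev(params, *condition.grid())
        params.w = w
        if scenario == "attribute":
            res = attribute_adapt_sequence(params, design)
            params_post = res.params_final
            Vin_traj, Z_traj, dc = res.Vin, res.Z, res.dC_norms
        elif scenario == "value":
            out = run_sequence(params, plasticity, gains, losses)
            params_post = params.copy()
            params_post.C = out["C"]
            Vin_traj, Z_traj = out["Vin"], out["Z"]
            dc = out["dC_norms"]
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        s = _summarize_run(condition, params, params_post, Vin_traj, (gains, losses))
        Z_post = s.pop("Z_post")
        dc_first, dc_last = float(np.mean(dc[:32])), float(np.mean(dc[-32:]))
        rows.append(RunSummary(
            responsive_pre=s["responsive_pre"], responsive_post=s["responsive_post"],
            enc_gain=s["enc_gain"], enc_loss=s["enc_loss"], enc_ev=s["enc_ev"],
            b_gain=s["b_gain"], b_loss=s["b_loss"], la_ratio=s["la_ratio"],
            readout_r2=r2, dc_norm_first=dc_first, dc_norm_last=dc_last,
        ))
        rec = {"evs": evs, "gains": gains, "losses": losses,
               "Z_post": Z_post, "params_post": params_post}
        if keep_arrays:
            rec.update({"Vin_traj": Vin_traj, "Z_traj": Z_traj,
                        "params_pre": params, "design": design})
        runs.append(rec)
    summaries = pd.DataFrame([vars(r) for r in rows])
    return summaries, runs


def ev_binned_unit_curves(Z, evs, n_bins: int = 9, sign_class: str = "+"):
    """Mean unit response per EV bin, pooled within a +EV / -EV unit class.

    Units are classed by the sign of their across-trial correlation with
    EV; units with response variance below 1e-8 are excluded.  Bins are
    equal-width within the realized EV range.  Returns ``(bin_centers,
    curve)`` or ``(bin_centers, None)`` when the class is empty.
    """
    if sign_class not in {"+", "-"}:
        raise ValueError("sign_class must be '+' or '-'")
    if n_bins < 2:
        raise ValueError("need at least 2 EV bins")
    Z = np.asarray(Z, float)
    evs = np.asarray(evs, float)
    var = Z.var(axis=0)
    active = var > 1e-8
    if not active.any():
        return None, None
    Za = Z[:, active]
    corr = np.array([np.corrcoef(Za[:, k], evs)[0, 1] for k in range(Za.shape[1])])
    members = corr > 0 if sign_class == "+" else corr < 0
    edges = np.linspace(evs.min(), evs.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if not members.any():
        return centers, None
    Zc = Za[:, members]
    idx = np.clip(np.digitize(evs, edges[1:-1]), 0, n_bins - 1)
    curve = np.array([
        Zc[idx == b].mean() if np.any(idx == b) else np.nan for b in range(n_bins)
    ])
    return centers, curve


def behavioral_sensitivities(params: NetworkParams, condition: RangeCondition):
    """Readout-value gradients per unit gain and per unit loss.

    OLS of the value landscape V(G, L) over the condition's grid on G and
    -L (plus intercept): ``b_gain`` is the value increase per unit gain,
    ``b_loss`` the value decrease per unit loss, and loss aversion is the
    ratio b_loss / b_gain (NaN-flagged unless both are positive).
    """
    g, l = condition.grid()
    _, _, _, V = forward_batch(params, g, l)
    A = np.column_stack([np.ones_like(g), g, -l])
    beta, _, _, _ = np.linalg.lstsq(A, V, rcond=None)
    b_g, b_l = float(beta[1]), float(beta[2])
    ratio = b_l / b_g if (b_g > 0 and b_l > 0) else np.nan
    return b_g, b_l, ratio


def range_grid_sweep(
    gain_uppers: Sequence[float],
    loss_uppers: Sequence[float],
    plasticity: PlasticityParams,
    n_runs: int = 100,
    seed: int = 0,
    scenario: str = "value",
    **net_kwargs,
) -> pd.DataFrame:
    """Sweep a grid of gain/loss upper bounds (all ranges start at 0).

    Returns one row per (gain_hi, loss_hi) cell with run-averaged
    encoding strengths, behavioral sensitivities and loss-aversion ratio.
    """
    rows = []
    for gi, g_hi in enumerate(gain_uppers):
        for li, l_hi in enumerate(loss_uppers):
            cond = RangeCondition(gain_range=(0.0, float(g_hi)),
                                  loss_range=(0.0, float(l_hi)))
            cell_seed = seed + 7919 * (gi * len(loss_uppers) + li + 1)
            summaries, _ = run_condition(
                cond, plasticity, n_runs=n_runs, seed=cell_seed,
                scenario=scenario, **net_kwargs,
            )
            m = summaries.mean(numeric_only=True)
            # condition-level loss aversion: ratio of run-mean sensitivities
            # (per-run ratios are heavy-tailed when sensitivities are small)
            ratio = m["b_loss"] / m["b_gain"] \
                if (m["b_gain"] > 0 and m["b_loss"] > 0) else np.nan
            rows.append({
                "gain_hi": g_hi, "loss_hi": l_hi,
                "enc_gain": m["enc_gain"], "enc_loss": m["enc_loss"],
                "enc_ev": m["enc_ev"], "b_gain": m["b_gain"],
                "b_loss": m["b_loss"],
                "la_ratio": float(ratio),
                "n_runs": n_runs, "seed": cell_seed,
            })
    return pd.DataFrame(rows)


def classify_value_cells(Z, choices, gamble_values, chosen_values, alpha_level=0.05):
    """Label integration units as choice / chosen-value / offer-value cells.

    A unit belongs to a (possibly overlapping) class when its across-trial
    Pearson correlation with the corresponding variable — binary choice
    (point-biserial), chosen value, gamble (offer) value — is significant
    at ``alpha_level``.  Constant units are left unclassified.  Returns a
    DataFrame of per-unit labels and a dict of class proportions.
    """
    Z = np.asarray(Z, float)
    n_t, n_z = Z.shape
    if n_t < 20:
        raise ValueError("need at least 20 trials to classify units")
    targets = {
        "choice": np.asarray(choices, float),
        "chosen_value": np.asarray(chosen_values, float),
        "offer_value": np.asarray(gamble_values, float),
    }
    rows = []
    for k in range(n_z):
        zk = Z[:, k]
        if zk.std() < 1e-12:
            rows.append({"unit": k, "choice": False, "chosen_value": False,
                         "offer_value": False, "classified": False})
            continue
        rec = {"unit": k}
        any_sig = False
        for name, tgt in targets.items():
            if tgt.std() < 1e-12:
                rec[name] = False
                continue
            r, p = stats.pearsonr(zk, tgt)
            rec[name] = bool(p < alpha_level)
            any_sig |= rec[name]
        rec["classified"] = any_sig
        rows.append(rec)
    labels = pd.DataFrame(rows)
    props = {
        name: float(labels[name].mean())
        for name in ("choice", "chosen_value", "offer_value")
    }
    props["unclassified"] = float((~labels["classified"]).mean())
    return labels, props


def noise_robustness_curve(
    params: NetworkParams,
    condition: RangeCondition,
    sds: Sequence[float],
    n_reps: int = 100,
    seed: int = 0,
    bias: float = 0.0,
):
    """Choice consistency under integration-layer noise, per noise sd.

    For each sd, the probability that the noisy choice sign(bias + V~)
    matches the noiseless choice, averaged over the condition's trials and
    ``n_reps`` noise draws.  1 at sd = 0, 0.5 in the large-noise limit.
    """
    g, l = condition.grid()
    _, _, Z, V = forward_batch(params, g, l)
    clean = np.sign(bias + V)
    rng = np.random.default_rng(seed)
    out = np.empty(len(sds))
    for s_i, sd in enumerate(sds):
        if sd < 0:
            raise ValueError("noise sd must be non-negative")
        eta = rng.normal(0.0, sd, size=(n_reps,) + Z.shape) if sd > 0 else \
            np.zeros((1,) + Z.shape)
        noisy = np.sign(bias + (Z[None] + eta) @ params.w)
        out[s_i] = float(np.mean(noisy == clean[None]))
    return np.asarray(out)
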