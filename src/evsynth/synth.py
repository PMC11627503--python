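"""Synthetic two-group gamble studies: designs, agents, cohorts, patterns.

Everything the pipeline consumes can be generated here so it runs
end-to-end with no download:

* the two study designs — "narrow" (16 gain levels $5-$20 x 16 loss
  levels $5-$20, every combination once across 256 trials) and "wide"
  (gains $10-$40 in steps of 2, i.e. the narrow gain levels doubled;
  losses unchanged), with seeded trial order and contiguous sessions;
* ground-truth choosers — a range-adapting network agent (the plastic
  two-layer network with a temperature-scaled EV readout) and a
  drifting-logistic agent with a programmable loss-aversion trajectory;
* two-group cohorts with agent parameters drawn from documented
  hyperpriors;
* multivariate "voxel" trial patterns that linearly mix integration-unit
  activity with session offsets and AR(1) trial noise at a given SNR;
* a BIDS-like events-TSV reader/writer, including the deposited
  dataset's column dialect.

Every generator is a pure function of its seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    MONEY_NORM,
    GambleTrial,
    NetworkParams,
    make_network,
    normalize_money,
    trials_to_arrays,
)
from .engine import run_sequence
from .plasticity import PlasticityParams
from .behavior import ChoiceDataset
from .simulation import train_readout_to_ev

__all__ = [
    "GroupDesignSpec",
    "gen_group_design",
    "PlasticANNAgent",
    "DriftingLogisticAgent",
    "make_plastic_agent",
    "make_drifting_agent",
    "simulate_choices",
    "SubjectRecord",
    "gen_cohort",
    "gen_voxel_patterns",
    "write_events_tsv",
    "read_events_tsv",
    "events_to_choice_dataset",
]

#: Default behavioral temperature multiplying the EV-trained readout of
#: ground-truth agents.  40 makes the implied logistic sensitivities about
#: 0.5 logit per dollar, which puts simulated choosers in the balanced-
#: accuracy regime (high 80s) observed in the re-analyzed studies.
DEFAULT_TEMPERATURE = 40.0

RESPONSE_TOKENS = ("strongly_accept", "weakly_accept",
                   "weakly_reject", "strongly_reject", "NoResp")


@dataclass(frozen=True)
class GroupDesignSpec:
    """Design of one study group: 16 x 16 factorial gamble levels."""

    group: str  # "narrow" | "wide"
    n_sessions: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.group not in ("narrow", "wide"):
            raise ValueError("group must be 'narrow' or 'wide'")
        if 256 % self.n_sessions:
            raise ValueError("n_sessions must divide 256")

    @property
    def gain_levels(self) -> np.ndarray:
        if self.group == "narrow":
            return np.arange(5.0, 21.0)           # $5..$20 step 1
        return np.arange(10.0, 41.0, 2.0)         # $10..$40 step 2

    @property
    def loss_levels(self) -> np.ndarray:
        return np.arange(5.0, 21.0)               # $5..$20 both groups

    @property
    def n_trials(self) -> int:
        return len(self.gain_levels) * len(self.loss_levels)


def gen_group_design(spec: GroupDesignSpec) -> list[GambleTrial]:
    """Full factorial, seeded shuffle, contiguous session blocks."""
    G, L = np.meshgrid(spec.gain_levels, spec.loss_levels, indexing="ij")
    g, l = G.ravel(), L.ravel()
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(spec.n_trials)
    per_session = spec.n_trials // spec.n_sessions
    return [
        GambleTrial(
            gain=float(g[o]), loss=float(l[o]),
            trial_index=t + 1, session=t // per_session + 1,
        )
        for t, o in enumerate(order)
    ]


# ---------------------------------------------------------------------
# ground-truth agents
# ---------------------------------------------------------------------

@dataclass
class PlasticANNAgent:
    """Range-adapting ground-truth chooser backed by the two-layer network."""

    params: NetworkParams
    plasticity: PlasticityParams
    bias: float = 0.0
    money_norm: float = MONEY_NORM

    def choice_probabilities(self, trials: Sequence[GambleTrial]):
        """Sequential p(accept) over a design; plasticity state evolves
        across trials.  Also returns the integration-layer trajectory."""
        gains, losses, _, _ = trials_to_arrays(trials)
        out = run_sequence(
            self.params, self.plasticity,
            gains / self.money_norm, losses / self.money_norm,
            bias=self.bias,
        )
        return out["P"], out["Z"]


@dataclass
class DriftingLogisticAgent:
    """Logistic chooser with per-trial sensitivity trajectories."""

    w0: float
    wG_traj: np.ndarray
    wL_traj: np.ndarray

    def choice_probabilities(self, trials: Sequence[GambleTrial]):
        gains, losses, _, _ = trials_to_arrays(trials)
        n = len(trials)
        if len(self.wG_traj) != n or len(self.wL_traj) != n:
            raise ValueError("sensitivity trajectories must match trial count")
        eta = self.w0 + self.wG_traj * gains - self.wL_traj * losses
        return 1.0 / (1.0 + np.exp(-eta)), None


def make_plastic_agent(
    seed: int,
    alpha: float,
    beta: float,
    bias: float = 0.0,
    design_spec: Optional[GroupDesignSpec] = None,
    n_x: int = 8,
    n_z: int = 16,
    temperature: float = DEFAULT_TEMPERATURE,
) -> PlasticANNAgent:
    """Build a ground-truth network agent with an EV-trained readout.

    The readout is trained on the agent's own (normalized) design grid and
    scaled by ``temperature`` so choices are realistically decisive rather
    than near-random.
    """
    spec = design_spec or GroupDesignSpec("narrow")
    params = make_network(n_x=n_x, n_z=n_z, seed=seed)
    G, L = np.meshgrid(normalize_money(spec.gain_levels),
                       normalize_money(spec.loss_levels), indexing="ij")
    # sum-zero readout: the agent's value signal stays drift-free while
    # adaptation recenters integration activities
    w, _, _ = train_readout_to_ev(params, G.ravel(), L.ravel(), sum_zero=True)
    params.w = w * temperature
    return PlasticANNAgent(
        params=params,
        plasticity=PlasticityParams(alpha=alpha, beta=beta),
        bias=bias,
    )


def make_drifting_agent(
    n_trials: int,
    lambda_start: float = 0.25,
    lambda_end: float = 0.41,
    wG: float = 0.25,
    w0: float = 0.0,
) -> DriftingLogisticAgent:
    """Logistic agent whose loss aversion drifts linearly over trials."""
    lam = np.linspace(lambda_start, lambda_end, n_trials)
    return DriftingLogisticAgent(
        w0=w0, wG_traj=np.full(n_trials, wG), wL_traj=wG * np.exp(lam),
    )


def simulate_choices(agent, design: Sequence[GambleTrial], seed: int = 0,
                     strong_margin: float = 0.25) -> ChoiceDataset:
    """Sample a 4-level response series from an agent's p(accept).

    Accept/reject is a Bernoulli draw from p; the strong/weak label splits
    on |p - 0.5| >= ``strong_margin``.  Downstream analyses binarize the
    response, so only the accept/reject split carries information.
    """
    p, _ = agent.choice_probabilities(design)
    rng = np.random.default_rng(seed)
    accept = (rng.random(len(p)) < p).astype(float)
    return ChoiceDataset(trials=list(design), accept=accept)


def response_labels(p, accept, strong_margin: float = 0.25):
    """Map (probability, sampled accept) pairs onto the 4-level vocabulary."""
    labels = []
    for pi, ai in zip(p, accept):
        strength = "strongly" if abs(pi - 0.5) >= strong_margin else "weakly"
        word = "accept" if ai == 1 else "reject"
        labels.append(f"{strength}_{word}")
    return labels


# ---------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    spec: GroupDesignSpec
    design: list
    dataset: ChoiceDataset
    agent: object
    truth: dict


DEFAULT_HYPERPRIORS = {
    "alpha": (0.05, 0.6),    # Uniform bounds
    "beta": (0.05, 0.5),     # Uniform bounds
    "bias_sd": 0.3,          # Normal(0, sd)
}


def gen_cohort(
    n_per_group: int,
    seed: int = 0,
    hyperpriors: Optional[dict] = None,
    agent_kind: str = "plastic",
    n_x: int = 8,
    n_z: int = 16,
) -> list[SubjectRecord]:
    """Two groups of subjects with fresh design shuffles and sampled agents.

    Plastic-network agents draw alpha ~ U[0.05, 0.6], beta ~ U[0.05, 0.5]
    and bias ~ N(0, 0.3) by default (``hyperpriors`` overrides; an alpha
    bound pair of (0, 0) yields a cohort of static agents).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    hp = dict(DEFAULT_HYPERPRIORS)
    if hyperpriors:
        hp.update(hyperpriors)
    rng = np.random.default_rng(seed)
    cohort = []
    sid = 0
    for group in ("narrow", "wide"):
        for _ in range(n_per_group):
            sid += 1
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = GroupDesignSpec(group, seed=sub_seed)
            design = gen_group_design(spec)
            if agent_kind == "plastic":
                alpha = float(rng.uniform(*hp["alpha"]))
                beta = float(rng.uniform(*hp["beta"]))
                bias = float(rng.normal(0.0, hp["bias_sd"]))
                agent = make_plastic_agent(
                    seed=sub_seed + 1, alpha=alpha, beta=beta, bias=bias,
                    design_spec=spec, n_x=n_x, n_z=n_z,
                )
                truth = {"alpha": alpha, "beta": beta, "bias": bias,
                         "seed": sub_seed + 1}
            elif agent_kind == "drifting":
                agent = make_drifting_agent(spec.n_trials)
                truth = {"lambda_start": 0.25, "lambda_end": 0.41}
            else:
                raise ValueError(f"unknown agent kind {agent_kind!r}")
            ds = simulate_choices(agent, design, seed=sub_seed + 2)
            ds.subject_id = f"sub-{sid:03d}"
            ds.group = group
            cohort.append(SubjectRecord(
                subject_id=ds.subject_id, group=group, spec=spec,
                design=design, dataset=ds, agent=agent, truth=truth,
            ))
    return cohort


# ---------------------------------------------------------------------
# synthetic multivariate trial patterns
# ---------------------------------------------------------------------

def gen_voxel_patterns(
    Z: np.ndarray,
    n_vox: int = 100,
    snr: float = 1.0,
    sessions=None,
    ar1_coef: float = 0.0,
    session_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic voxel-by-trial patterns mixing integration-unit activity.

    Y = M Z^T + session offsets + AR(1) noise, with M a seeded random
    mixing matrix (n_vox x n_z).  The noise innovation variance is set so
    that var(signal) / var(noise) = snr^2 per voxel (stationary AR(1)
    variance).  ``session_sd`` scales per-voxel, per-session offsets
    relative to the signal's across-trial standard deviation.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if not abs(ar1_coef) < 1:
        raise ValueError("ar1_coef must satisfy |ar1_coef| < 1")
    Z = np.asarray(Z, float)
    n_t, n_z = Z.shape
    rng = np.random.default_rng(seed)
    M = rng.normal(0.0, 1.0 / np.sqrt(n_z), size=(n_vox, n_z))
    signal = M @ Z.T                                       # (n_vox, n_t)
    sig_sd = signal.std(axis=1, keepdims=True)
    sig_sd = np.where(sig_sd < 1e-12, 1e-12, sig_sd)
    noise_sd = sig_sd / snr
    innov_sd = noise_sd * np.sqrt(1.0 - ar1_coef ** 2)
    eps = np.empty((n_vox, n_t))
    innov = rng.normal(0.0, 1.0, size=(n_vox, n_t)) * innov_sd
    eps[:, 0] = rng.normal(0.0, 1.0, size=n_vox) * noise_sd[:, 0]
    for t in range(1, n_t):
        eps[:, t] = ar1_coef * eps[:, t - 1] + innov[:, t]
    Y = signal + eps
    if sessions is not None:
        sessions = np.asarray(sessions)
        for s in np.unique(sessions):
            offs = rng.normal(0.0, session_sd, size=(n_vox, 1)) * sig_sd
            Y[:, sessions == s] += offs
    return Y


# ---------------------------------------------------------------------
# events-table input/output
# ---------------------------------------------------------------------

_NATIVE_COLS = ["onset", "duration", "gain", "loss", "response", "session"]
_NARPS_RESPONSE = {
    "strongly_accept": 1.0, "weakly_accept": 1.0,
    "weakly_reject": 0.0, "strongly_reject": 0.0,
    "NoResp": np.nan,
}


def dataset_to_events(data: ChoiceDataset, p=None, iti: float = 7.0,
                      duration: float = 4.0) -> pd.DataFrame:
    """Native events table for a choice dataset (one row per trial)."""
    gains, losses, _, sessions, accept = data.arrays()
    if p is None:
        labels = ["weakly_accept" if a == 1 else "weakly_reject"
                  if np.isfinite(a) else "NoResp" for a in accept]
    else:
        labels = [
            lab if np.isfinite(a) else "NoResp"
            for lab, a in zip(response_labels(p, accept), accept)
        ]
    return pd.DataFrame({
        "onset": np.arange(len(gains)) * iti,
        "duration": duration,
        "gain": gains,
        "loss": losses,
        "response": labels,
        "session": sessions,
    })


def write_events_tsv(path, table: pd.DataFrame) -> None:
    """Write a native-dialect events TSV (lossless round-trip)."""
    missing = [c for c in _NATIVE_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"events table missing required columns: {missing}")
    table[_NATIVE_COLS].to_csv(path, sep="\t", index=False)


def read_events_tsv(path_or_paths, dialect: str = "native") -> pd.DataFrame:
    """Read an events TSV into the native layout.

    ``dialect="native"`` expects the columns this package writes.
    ``dialect="narps"`` accepts one or more per-run files with columns
    onset, duration, gain, loss, participant_response (the deposited
    dataset's layout); files are concatenated in the given run order and
    labeled with consecutive session numbers.  Unknown response tokens
    raise a parse error naming the token.
    """
    paths = [path_or_paths] if isinstance(path_or_paths, (str, Path)) else list(path_or_paths)
    frames = []
    for run, path in enumerate(paths, start=1):
        df = pd.read_csv(path, sep="\t")
        if dialect == "native":
            missing = [c for c in _NATIVE_COLS if c not in df.columns]
            if missing:
                raise ValueError(f"missing required column(s): {missing}")
            frames.append(df[_NATIVE_COLS])
        elif dialect == "narps":
            required = ["onset", "duration", "gain", "loss", "participant_response"]
            missing = [c for c in required if c not in df.columns]
            if missing:
                raise ValueError(f"missing required column(s): {missing}")
            out = df[required].rename(columns={"participant_response": "response"})
            out["session"] = run
            frames.append(out)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    table = pd.concat(frames, ignore_index=True)
    bad = set(table["response"]) - set(RESPONSE_TOKENS)
    if bad:
        raise ValueError(f"unknown response token(s): {sorted(bad)}")
    return table


def events_to_choice_dataset(table: pd.DataFrame, subject_id: str = "s0",
                             group: Optional[str] = None) -> ChoiceDataset:
    """Binarize the 4-level response vocabulary into a choice dataset.

    Strong and weak accepts map to 1, rejects to 0, no-response to NaN
    (excluded from fits downstream).
    """
    accept = np.array([_NARPS_RESPONSE[r] for r in table["response"]])
    trials = [
        GambleTrial(gain=float(r.gain), loss=float(r.loss),
                    trial_index=i + 1, session=int(r.session))
        for i, r in enumerate(table.itertuples())
    ]
    return ChoiceDataset(trials=trials, accept=accept,
                         subject_id=subject_id, group=group)
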