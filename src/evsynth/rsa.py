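"""Representational similarity machinery.

Trial-pair dissimilarity matrices (RDMs, 1 - Pearson correlation between
multivariate activity patterns), confound corrections (session-mean
projection, per-delay detrending against temporal autocorrelation),
attribute/EV encoding strengths (regression of pairwise dissimilarity on
pairwise attribute distance), binned RDMs, and model-vs-data RDM
comparison with Fisher-z group inference.

Pattern matrices ``Y`` are units-by-trials (rows = units or voxels,
columns = trials); RDMs are trials-by-trials.  Because RDMs are built
from correlations they are invariant to affine transformations of the
per-trial patterns, which decouples these analyses from univariate mean
activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RDM",
    "EncodingStrengths",
    "project_out_sessions",
    "compute_rdm",
    "delay_detrend",
    "attribute_encoding_strength",
    "ev_encoding_strength",
    "binned_rdm",
    "rdm_similarity",
    "group_level_test",
]


@dataclass
class RDM:
    """Symmetric trial-pair dissimilarity matrix with provenance flags."""

    D: np.ndarray
    session_projected: bool = False
    delay_detrended: bool = False

    @property
    def n_trials(self) -> int:
        return self.D.shape[0]

    @property
    def corrected(self) -> bool:
        return self.session_projected or self.delay_detrended

    def lower_triangle(self) -> np.ndarray:
        """Vectorized strict lower triangle (may contain NaN for flagged pairs)."""
        i, j = np.tril_indices(self.n_trials, k=-1)
        return self.D[i, j]


@dataclass(frozen=True)
class EncodingStrengths:
    """Dissimilarity-per-unit-attribute regression slopes.

    Gain and loss slopes come from one joint regression (|dG| and |dL|
    concurrently plus intercept); the EV slope from a separate regression
    to avoid collinearity with its constituents.  Standard errors are
    nominal OLS values: trial pairs sharing a trial are not independent,
    so they understate uncertainty and are reported for reference only.
    """

    slope_gain: float
    slope_loss: float
    slope_ev: float
    se_gain: float
    se_loss: float
    se_ev: float
    n_pairs: int


def project_out_sessions(Y: np.ndarray, sessions) -> np.ndarray:
    """Remove per-unit session means (projection onto the session design's
    null space).  Idempotent; with a single session this is an identity
    (with a warning)."""
    Y = np.asarray(Y, dtype=float)
    sessions = np.asarray(sessions)
    if Y.shape[1] != sessions.shape[0]:
        raise ValueError("session labels must match the number of trials")
    labels = np.unique(sessions)
    if labels.size < 2:
        warnings.warn("only one session: session projection is an identity")
        return Y.copy()
    out = Y.copy()
    for s in labels:
        mask = sessions == s
        out[:, mask] -= out[:, mask].mean(axis=1, keepdims=True)
    return out


def compute_rdm(Y: np.ndarray) -> RDM:
    """Raw RDM: D(t, t') = 1 - corr(Y[:, t], Y[:, t'])."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 units to correlate patterns")
    sd = Y.std(axis=0)
    constant = sd < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(Y.T)
    D = 1.0 - R
    if constant.any():
        D[constant, :] = np.nan
        D[:, constant] = np.nan
    np.fill_diagonal(D, 0.0)
    return RDM(D=D)


def delay_detrend(rdm: RDM, trial_order=None) -> RDM:
    """Subtract the mean dissimilarity at each inter-trial delay.

    ``trial_order`` gives each column's position in the presentation
    sequence (default: columns already in presentation order).  Delay is
    the absolute difference of positions on the concatenated trial index;
    pairs spanning sessions use the same index arithmetic.  After the
    correction the mean of entries at every delay is zero, and entries
    may be negative.
    """
    n = rdm.n_trials
    order = np.arange(n) if trial_order is None else np.asarray(trial_order)
    delay = np.abs(order[:, None] - order[None, :])
    D = rdm.D.copy()
    off = ~np.eye(n, dtype=bool)
    for d in np.unique(delay[off]):
        mask = (delay == d) & off
        vals = D[mask]
        m = np.nanmean(vals)
        D[mask] = vals - m
    return RDM(D=D, session_projected=rdm.session_projected, delay_detrended=True)


def _triangle_regression(y, X):
    """OLS with intercept on lower-triangle entries; NaNs dropped pairwise."""
    keep = np.isfinite(y)
    for col in X:
        keep &= np.isfinite(col)
    y = y[keep]
    A = np.column_stack([np.ones(y.shape[0])] + [col[keep] for col in X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("degenerate (collinear) distance regressors")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = max(y.shape[0] - A.shape[1], 1)
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    return beta, np.sqrt(np.diag(cov)), y.shape[0]


def attribute_encoding_strength(rdm: RDM, gains, losses) -> EncodingStrengths:
    """Joint regression of pairwise dissimilarity on |dG| and |dL|.

    The slopes are the neural encoding strengths of gains and losses (the
    EV slope is filled in by a separate call to
    :func:`ev_encoding_strength`; here it is NaN).
    """
    gains = np.asarray(gains, dtype=float)
    losses = np.asarray(losses, dtype=float)
    i, j = np.tril_indices(rdm.n_trials, k=-1)
    y = rdm.D[i, j]
    dg = np.abs(gains[i] - gains[j])
    dl = np.abs(losses[i] - losses[j])
    beta, se, n = _triangle_regression(y, [dg, dl])
    return EncodingStrengths(
        slope_gain=float(beta[1]), slope_loss=float(beta[2]), slope_ev=np.nan,
        se_gain=float(se[1]), se_loss=float(se[2]), se_ev=np.nan, n_pairs=n,
    )


def ev_encoding_strength(rdm: RDM, evs) -> tuple[float, float]:
    """Single-regressor version on |dEV|; returns (slope, nominal se)."""
    evs = np.asarray(evs, dtype=float)
    i, j = np.tril_indices(rdm.n_trials, k=-1)
    y = rdm.D[i, j]
    dev = np.abs(evs[i] - evs[j])
    beta, se, _ = _triangle_regression(y, [dev])
    return float(beta[1]), float(se[1])


def binned_rdm(rdm: RDM, values, levels=None) -> np.ndarray:
    """Average trial-pair dissimilarity between (and within) value levels.

    ``values`` assigns each trial to a level of the binning attribute
    (gain, loss, or EV); ``levels`` fixes the level order (default: sorted
    unique values).  Entry (a, b) averages all cross pairs; the diagonal
    averages within-level pairs (self-pairs excluded).  Level pairs with
    no trial pair are NaN.
    """
    values = np.asarray(values)
    if levels is None:
        levels = np.unique(values)
    L = len(levels)
    out = np.full((L, L), np.nan)
    groups = [np.flatnonzero(values == lev) for lev in levels]
    for a in range(L):
        for b in range(a + 1):
            ia, ib = groups[a], groups[b]
            if ia.size == 0 or ib.size == 0:
                continue
            block = rdm.D[np.ix_(ia, ib)]
            if a == b:
                if ia.size < 2:
                    continue
                iu = np.triu_indices(ia.size, k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            m = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
            out[a, b] = out[b, a] = m
    return out


def rdm_similarity(rdm_model, rdm_data) -> tuple[float, float]:
    """Pearson r between vectorized lower triangles, and its Fisher z.

    Accepts :class:`RDM` objects or plain square matrices (e.g. binned
    RDMs); missing entries are dropped pairwise.
    """
    A = rdm_model.D if isinstance(rdm_model, RDM) else np.asarray(rdm_model, float)
    B = rdm_data.D if isinstance(rdm_data, RDM) else np.asarray(rdm_data, float)
    if A.shape != B.shape:
        raise ValueError("RDM shapes must match")
    i, j = np.tril_indices(A.shape[0], k=-1)
    a, b = A[i, j], B[i, j]
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 valid trial pairs")
    r = float(np.corrcoef(a[keep], b[keep])[0, 1])
    r_clip = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r, float(np.arctanh(r_clip))


def group_level_test(fisher_zs) -> tuple[float, float, int]:
    """One-sample t-test on subjects' Fisher-transformed RDM correlations.

    Returns (t, two-sided p, dof).
    """
    z = np.asarray(fisher_zs, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 2:
        raise ValueError("need at least 2 subjects")
    t, p = stats.ttest_1samp(z, 0.0)
    return float(t), float(p), z.size - 1
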