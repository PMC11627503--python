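"""JIT-compiled sequential simulator used by the Monte-Carlo harnesses.

This is a fast path for running the two-layer network with (or without)
self-organized plasticity over a whole trial sequence.  It mirrors, step
for step, the reference implementation in
:func:`evsynth.plasticity.adapt_sequence`; the test suite asserts
bit-level agreement between the two.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import NetworkParams
from .plasticity import PlasticityParams

__all__ = ["run_sequence", "run_sequence_raw"]


@njit(cache=True)
def run_sequence_raw(mu_x, sig_x, mu_z, sig_z, C0, w, bias,
                     alpha, beta, gains, losses):
    """Sequential forward + plasticity loop (flattened parameter arrays).

    ``mu_x``/``sig_x`` are attribute-major flattened (gain units first),
    length n_ux; gains/losses are canonical-domain inputs per trial.
    Returns (P, X, Vin, Z, V, C_final, dC_norms).
    """
    n_t = gains.shape[0]
    n_ux, n_z = C0.shape
    n_x = n_ux // 2
    C = C0.copy()
    dC = np.zeros((n_ux, n_z))
    dC_norms = np.zeros(n_t)
    P = np.empty(n_t)
    X = np.empty((n_t, n_ux))
    Vin = np.empty((n_t, n_z))
    Z = np.empty((n_t, n_z))
    V = np.empty(n_t)
    x = np.empty(n_ux)
    adapt = alpha > 0.0 and beta > 0.0
    for t in range(n_t):
        for j in range(n_x):
            x[j] = 1.0 / (1.0 + np.exp((mu_x[j] - gains[t]) / sig_x[j]))
            x[n_x + j] = 1.0 / (1.0 + np.exp((mu_x[n_x + j] - losses[t]) / sig_x[n_x + j]))
        for k in range(n_z):
            vk = 0.0
            for ij in range(n_ux):
                vk += C[ij, k] * x[ij]
            Vin[t, k] = vk
            Z[t, k] = 1.0 / (1.0 + np.exp((mu_z[k] - vk) / sig_z[k]))
        Vt = 0.0
        for k in range(n_z):
            Vt += w[k] * Z[t, k]
        V[t] = Vt
        P[t] = 1.0 / (1.0 + np.exp(-(bias + Vt)))
        for ij in range(n_ux):
            X[t, ij] = x[ij]
        if adapt:
            acc = 0.0
            for k in range(n_z):
                gk = (1.0 - 2.0 * Z[t, k]) / sig_z[k]
                for ij in range(n_ux):
                    d = alpha * (1.0 - beta) * dC[ij, k] + alpha * beta * gk * x[ij]
                    dC[ij, k] = d
                    C[ij, k] += d
                    acc += d * d
            dC_norms[t] = np.sqrt(acc)
    return P, X, Vin, Z, V, C, dC_norms


def run_sequence(params: NetworkParams, plasticity: PlasticityParams,
                 gains, losses, bias=None):
    """Convenience wrapper taking package-level parameter objects.

    Returns a dict with per-trial choice probabilities ``P`` (using the
    decision bias), activities ``X``, ``Vin``, ``Z``, values ``V``, the
    final connectivity ``C`` and per-trial update norms ``dC_norms``.
    """
    gains = np.ascontiguousarray(gains, dtype=float)
    losses = np.ascontiguousarray(losses, dtype=float)
    b = params.bias if bias is None else float(bias)
    P, X, Vin, Z, V, C, dC_norms = run_sequence_raw(
        np.ascontiguousarray(params.attr_mu.ravel()),
        np.ascontiguousarray(params.attr_sigma.ravel()),
        np.ascontiguousarray(params.z_mu),
        np.ascontiguousarray(params.z_sigma),
        np.ascontiguousarray(params.C),
        np.ascontiguousarray(params.w),
        b,
        float(plasticity.alpha),
        float(plasticity.beta),
        gains,
        losses,
    )
    return {"P": P, "X": X, "Vin": Vin, "Z": Z, "V": V, "C": C,
            "dC_norms": dC_norms}
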