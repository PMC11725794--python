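"""Gauss-Hermite quadrature kernels for max-of-Gaussians choice probabilities.

The probability that choice ``n`` wins a 4AFC race of unit-variance Gaussian
evidence samples with means ``m_i * delta`` is

    P(n) = E_x[ prod_{i != n} Phi(x + delta * (m_n - m_i)) ],   x ~ N(0, 1)

evaluated here with probabilists' Gauss-Hermite quadrature.  The fused numba
kernel computes, per trial, the probability of the *selected* choice and its
partial derivatives with respect to the three evidence-mean gaps -- the inner
loop of every model fit.  A pure-numpy implementation of the identical
arithmetic is kept both as a fallback and as an in-suite cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr

_SQRT2PI = math.sqrt(2.0 * math.pi)
_INV_SQRT2 = 1.0 / math.sqrt(2.0)

_node_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite nodes and normalized weights.

    Returns ``(x, w)`` such that ``E[g(X)] ~= sum_k w_k g(x_k)`` for
    ``X ~ N(0, 1)``.
    """
    if n not in _node_cache:
        x, w = np.polynomial.hermite_e.hermegauss(n)
        _node_cache[n] = (x, w / _SQRT2PI)
    return _node_cache[n]


def selected_prob_grad_numpy(msel, mfoil, delta, nodes, weights):
    """Per-trial P(selected) and dP/da_j for a_j = delta*(m_sel - m_foil_j).

    Parameters are the selected-choice similarity ``msel`` (T,), the three
    foil similarities ``mfoil`` (T, 3), and the sensitivity ``delta``.
    Returns ``(P (T,), q (T, 3))`` with ``q[:, j] = dP/da_j``.
    """
    a = delta * (msel[:, None] - mfoil)
    z = nodes[None, None, :] + a[:, :, None]
    c = ndtr(z)
    phi = np.exp(-0.5 * z * z) / _SQRT2PI
    # leave-one-out products, written out for the 3-foil case (stable when a
    # cdf underflows to 0; no division)
    p01 = c[:, 0, :] * c[:, 1, :]
    prod_all = p01 * c[:, 2, :]
    po = np.stack(
        [c[:, 1, :] * c[:, 2, :], c[:, 0, :] * c[:, 2, :], p01], axis=1
    )
    P = prod_all @ weights
    q = np.einsum("tjk,tjk,k->tj", phi, po, weights)
    return P, q


try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _selected_prob_grad_numba(msel, mfoil, delta, nodes, weights, out_p, out_q):
        T = msel.shape[0]
        K = nodes.shape[0]
        inv_sqrt2pi = 1.0 / _SQRT2PI
        for t in range(T):
            a0 = delta * (msel[t] - mfoil[t, 0])
            a1 = delta * (msel[t] - mfoil[t, 1])
            a2 = delta * (msel[t] - mfoil[t, 2])
            p = 0.0
            q0 = 0.0
            q1 = 0.0
            q2 = 0.0
            for k in range(K):
                x = nodes[k]
                wk = weights[k]
                z0 = x + a0
                z1 = x + a1
                z2 = x + a2
                c0 = 0.5 * (1.0 + math.erf(z0 * _INV_SQRT2))
                c1 = 0.5 * (1.0 + math.erf(z1 * _INV_SQRT2))
                c2 = 0.5 * (1.0 + math.erf(z2 * _INV_SQRT2))
                p += wk * c0 * c1 * c2
                q0 += wk * math.exp(-0.5 * z0 * z0) * inv_sqrt2pi * c1 * c2
                q1 += wk * math.exp(-0.5 * z1 * z1) * inv_sqrt2pi * c0 * c2
                q2 += wk * math.exp(-0.5 * z2 * z2) * inv_sqrt2pi * c0 * c1
            out_p[t] = p
            out_q[t, 0] = q0
            out_q[t, 1] = q1
            out_q[t, 2] = q2

    def selected_prob_grad_numba(msel, mfoil, delta, nodes, weights):
        out_p = np.empty(msel.shape[0])
        out_q = np.empty((msel.shape[0], 3))
        _selected_prob_grad_numba(
            np.ascontiguousarray(msel, dtype=np.float64),
            np.ascontiguousarray(mfoil, dtype=np.float64),
            float(delta),
            nodes,
            weights,
            out_p,
            out_q,
        )
        return out_p, out_q

    HAVE_NUMBA = True
    selected_prob_grad = selected_prob_grad_numba
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
    selected_prob_grad = selected_prob_grad_numpy
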