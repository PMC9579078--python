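"""Elementary symmetric functions of item easiness parameters.

The conditional likelihood of a Rasch-type model involves the elementary
symmetric functions (ESF) gamma_r of the easiness values eps_j = exp(-b_j):

    gamma_r(eps) = sum over all r-subsets S of {1..J} of prod_{j in S} eps_j.

They are computed with the stable summation recursion

    gamma_r^{(items 1..m)} = gamma_r^{(1..m-1)} + eps_m * gamma_{r-1}^{(1..m-1)},

never by subset enumeration. First partial derivatives are the leave-one-out
ESFs, d gamma_r / d eps_j = gamma_{r-1}^{(without j)}; second partials the
leave-two-out ESFs. Both are obtained by re-running the same recursion on the
reduced easiness vectors, which keeps all intermediate quantities positive.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError


def _gamma(eps: np.ndarray) -> np.ndarray:
    """ESF values gamma_0..gamma_J by the summation recursion."""
    j = eps.shape[0]
    g = np.zeros(j + 1)
    g[0] = 1.0
    for m in range(j):
        g[1 : m + 2] += eps[m] * g[: m + 1].copy()
    return g


def esf(eps, derivatives: int = 0):
    """Elementary symmetric functions gamma_0..gamma_J and partial derivatives.

    Parameters
    ----------
    eps : array-like of shape (J,)
        Positive easiness values.
    derivatives : {0, 1, 2}
        Order of partial derivatives to return.

    Returns
    -------
    gamma : ndarray of shape (J + 1,)
        ``gamma[r]`` is the order-r ESF; ``gamma[0] == 1``.
    d1 : ndarray of shape (J + 1, J), if ``derivatives >= 1``
        ``d1[r, j] = d gamma_r / d eps_j`` (the leave-one-out ESF of order r-1).
    d2 : ndarray of shape (J + 1, J, J), if ``derivatives == 2``
        ``d2[r, j, k] = d^2 gamma_r / d eps_j d eps_k``; the diagonal is 0.
    """
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 1 or eps.shape[0] < 1:
        raise DataError("eps must be a 1-d vector of easiness values")
    if not np.all(np.isfinite(eps)) or np.any(eps <= 0):
        raise DataError("easiness values must be positive and finite")
    if derivatives not in (0, 1, 2):
        raise ValueError("derivatives must be 0, 1 or 2")

    j = eps.shape[0]
    gamma = _gamma(eps)
    if derivatives == 0:
        return gamma

    d1 = np.zeros((j + 1, j))
    loo = {}
    for a in range(j):
        g_a = _gamma(np.delete(eps, a))
        loo[a] = g_a
        d1[1:, a] = g_a  # d gamma_r / d eps_a = gamma^{(a)}_{r-1}
    if derivatives == 1:
        return gamma, d1

    d2 = np.zeros((j + 1, j, j))
    for a in range(j):
        for b in range(a + 1, j):
            g_ab = _gamma(np.delete(eps, [a, b]))
            d2[2:, a, b] = g_ab
            d2[2:, b, a] = g_ab
    return gamma, d1, d2
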