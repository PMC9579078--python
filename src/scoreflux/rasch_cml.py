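"""Conditional maximum likelihood estimation of the dichotomous Rasch model.

Conditioning on the raw score r_i removes the person parameter: with easiness
eps_j = exp(-b_j) the conditional probability of response pattern u_i given
r_i is prod_j eps_j^{u_ij} / gamma_{r_i}(eps), where gamma_r is the order-r
elementary symmetric function. Persons with raw score 0 or J have a constant
conditional likelihood and contribute nothing to estimation (they are kept in
N so row indices stay aligned with covariates).

Identification fixes the first item's difficulty at 0; the free parameters
are b_2..b_J, maximized by Newton iterations with the analytic ESF-based
gradient and Hessian.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError, EstimationError
from .esf import esf
from .models import ModelFit, item_param_labels
from .response import ResponseMatrix


def _check_dichotomous(resp: ResponseMatrix) -> None:
    if not resp.is_dichotomous:
        raise DataError("the Rasch model requires dichotomous (0/1) items")
    u = resp.values
    for j in range(resp.n_items):
        col = u[:, j]
        if col.min() == col.max():
            raise EstimationError(
                f"item {resp.item_names[j]!r} has no variance (all responses "
                f"{col[0]}); its difficulty is not estimable"
            )


def _score_counts(resp: ResponseMatrix):
    """Raw-score counts n_r and informative item margins S_j."""
    u = resp.values
    j = resp.n_items
    r = resp.raw_scores()
    informative = (r > 0) & (r < j)
    n_r = np.bincount(r[informative], minlength=j + 1).astype(float)
    s_j = u[informative].sum(axis=0).astype(float)
    return r, informative, n_r, s_j


def _expected_response_table(b: np.ndarray):
    """pi[r, j] = expected response to item j of a person with raw score r."""
    eps = np.exp(-b)
    gamma, d1, d2 = esf(eps, derivatives=2)
    pi = eps[None, :] * d1 / gamma[:, None]
    return eps, gamma, d1, d2, pi


def conditional_loglik(b: np.ndarray, n_r: np.ndarray, s_j: np.ndarray) -> float:
    gamma = esf(np.exp(-b))
    return float(-(b * s_j).sum() - (n_r * np.log(gamma)).sum())


def fit_rasch_cml(resp: ResponseMatrix, maxit: int = 100, tol: float = 1e-8) -> ModelFit:
    """Fit the Rasch model by CML; returns a ModelFit with difficulties b_2..b_J.

    ``tol`` is the sup-norm of the conditional score at which Newton stops.
    """
    _check_dichotomous(resp)
    j = resp.n_items
    r, informative, n_r, s_j = _score_counts(resp)
    if informative.sum() == 0:
        raise EstimationError("no informative response patterns (all raw scores 0 or J)")

    b = np.zeros(j)
    free = np.arange(1, j)
    converged = False
    it = 0
    ll = conditional_loglik(b, n_r, s_j)
    for it in range(1, maxit + 1):
        eps, gamma, d1, d2, pi = _expected_response_table(b)
        grad = n_r @ pi - s_j  # d loglik / d b_j
        if np.max(np.abs(grad[free])) < tol:
            converged = True
            break
        # Hessian of the conditional log-likelihood w.r.t. difficulties
        cross = (eps[None, :, None] * eps[None, None, :]) * d2 / gamma[:, None, None]
        h = -(np.einsum("r,rjk->jk", n_r, cross) - np.einsum("r,rj,rk->jk", n_r, pi, pi))
        np.fill_diagonal(h, -(n_r @ (pi * (1.0 - pi))))
        step = np.linalg.solve(h[np.ix_(free, free)], grad[free])
        # step halving on the (concave) conditional log-likelihood
        scale = 1.0
        for _ in range(30):
            b_new = b.copy()
            b_new[free] -= scale * step
            ll_new = conditional_loglik(b_new, n_r, s_j)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        b = b_new
        ll = ll_new

    params = b[free].copy()
    cl = caselik_rasch_cml(params, resp)
    fit = ModelFit(
        model="rasch_cml",
        params=params,
        param_labels=item_param_labels("rasch_cml", resp.n_categories, resp.item_names),
        loglik=float(cl.sum()),
        caselik=cl,
        converged=converged,
        n_iter=it,
        identification="difficulty of item 1 fixed at 0",
        n_categories=resp.n_categories.copy(),
    )
    return fit


def caselik_rasch_cml(params: np.ndarray, resp: ResponseMatrix) -> np.ndarray:
    """Per-person conditional log-likelihood at difficulties (0, params)."""
    j = resp.n_items
    params = np.asarray(params, dtype=float)
    if params.shape != (j - 1,):
        raise DataError(f"expected {j - 1} free difficulties, got {params.shape}")
    b = np.concatenate([[0.0], params])
    u = resp.values
    r = resp.raw_scores()
    gamma = esf(np.exp(-b))
    out = -(u @ b) - np.log(gamma)[r]
    out[(r == 0) | (r == j)] = 0.0
    return out


def scores_rasch_cml_values(fit: ModelFit, resp: ResponseMatrix) -> np.ndarray:
    """Case-wise conditional score contributions, one column per free difficulty.

    Entry (i, j) is pi_{r_i j} - u_ij: the conditional expectation of the
    response given the raw score minus the observed response, i.e. the
    derivative of person i's conditional log-likelihood w.r.t. b_j.
    """
    if fit.model != "rasch_cml":
        raise TypeError(f"scores_rasch_cml expects a rasch_cml fit, got {fit.model!r}")
    j = resp.n_items
    b = np.concatenate([[0.0], fit.params])
    _, _, _, _, pi = _expected_response_table(b)
    r = resp.raw_scores()
    s = pi[r] - resp.values
    s[(r == 0) | (r == j)] = 0.0
    return s[:, 1:]
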