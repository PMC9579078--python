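"""Marginal maximum likelihood estimation of 1PL, 2PL and GPCM by EM.

The latent trait is integrated out against a normal distribution on a fixed
Gauss-Hermite grid (default 61 nodes). Without impact the trait is N(0, 1);
with impact each group g has its own N(mu_g, sigma_g^2), the reference group
fixed at N(0, 1) for identification and the remaining means/variances
estimated as free parameters.

E-step: posterior node weights P(theta_q | u_i, Psi) per person on the
person's group grid. M-step: per-item weighted likelihood maximization on the
pooled grid (logistic for 1PL/2PL, adjacent-category logistic for the GPCM)
plus closed-form posterior-moment updates for the group distributions.

The item response functions:

    2PL:   P(u_ij = 1 | theta) = exp(a_j theta + d_j) / (1 + exp(a_j theta + d_j))
    GPCM:  P(u_ij = k | theta) proportional to exp(k a_j theta + sum_{v<=k} d_jv)

with the empty sum for k = 0, so a 2-category GPCM item is exactly a 2PL item.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, logsumexp

from .errors import ConvergenceWarning, DataError, EstimationError
from .models import (
    GroupImpact,
    ModelFit,
    Quadrature,
    impact_param_labels,
    item_param_labels,
    n_item_params,
    unpack_mml,
)
from .response import ResponseMatrix


def irf_2pl(a, d, theta):
    """2PL item response function exp(a*theta + d) / (1 + exp(a*theta + d))."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return expit(a * theta + d)


def gpcm_logprobs(a: float, d: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Log category probabilities of a GPCM item, shape ``theta.shape + (K+1,)``.

    Category k has log-numerator ``k * a * theta + cumsum(d)_k`` (0 for k=0);
    normalization by log-sum-exp keeps large logits finite.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    theta = np.asarray(theta, dtype=float)
    k = np.arange(d.shape[0] + 1, dtype=float)
    cum_d = np.concatenate([[0.0], np.cumsum(d)])
    z = k * (a * theta[..., None]) + cum_d
    return z - logsumexp(z, axis=-1, keepdims=True)


def gpcm_category_probs(a, d, theta):
    """GPCM category probabilities; reduces to ``(1-p, p)`` of the 2PL for K=1."""
    return np.exp(gpcm_logprobs(float(a), d, np.asarray(theta, dtype=float)))


def _group_setup(resp: ResponseMatrix, impact):
    """Resolve the impact argument to a per-person group index, or None."""
    if impact is None:
        return None, ("all",), np.zeros(resp.n_persons, dtype=int)
    impact = np.asarray(impact)
    if impact.shape[0] != resp.n_persons:
        raise DataError("impact vector length does not match the number of persons")
    names = [str(v) for v in dict.fromkeys(impact.tolist())]  # order of appearance
    if len(names) < 2:
        warnings.warn(
            "impact grouping has a single level and is ignored", UserWarning, stacklevel=3
        )
        return None, ("all",), np.zeros(resp.n_persons, dtype=int)
    lookup = {name: g for g, name in enumerate(names)}
    idx = np.array([lookup[str(v)] for v in impact.tolist()], dtype=int)
    return impact, tuple(names), idx


def _check_categories(resp: ResponseMatrix, model: str) -> None:
    u = resp.values
    if model in ("onepl", "twopl") and not resp.is_dichotomous:
        raise DataError(f"the {model.upper()} model requires dichotomous items")
    for j in range(resp.n_items):
        counts = np.bincount(u[:, j], minlength=int(resp.n_categories[j]))
        missing = np.flatnonzero(counts == 0)
        if missing.size:
            raise EstimationError(
                f"item {resp.item_names[j]!r}: category {missing[0]} is never "
                "observed; its parameters are not estimable"
            )


def _item_logprob_tables(a, d, nodes_by_group):
    """Per item, per group: (Q, K_j+1) log category probabilities."""
    tables = []
    for j in range(len(d)):
        tables.append([gpcm_logprobs(a[j], d[j], nodes) for nodes in nodes_by_group])
    return tables


def _estep(u, group_idx, tables, log_w, n_groups):
    """Posterior node weights and per-person marginal log-likelihood."""
    n = u.shape[0]
    q = log_w.shape[0]
    post = np.zeros((n, q))
    ll = np.empty(n)
    for g in range(n_groups):
        rows = np.flatnonzero(group_idx == g)
        if rows.size == 0:
            continue
        lp = np.zeros((rows.size, q))
        for j, table in enumerate(tables):
            lp += table[g][:, u[rows, j]].T
        lp += log_w[None, :]
        ll_g = logsumexp(lp, axis=1)
        post[rows] = np.exp(lp - ll_g[:, None])
        ll[rows] = ll_g
    return post, ll


def _neg_expected_item_ll(x, theta, counts):
    """Expected-complete-data negative log-likelihood of one GPCM/2PL item
    with slope x[0], intercepts x[1:], node locations theta and expected
    response counts ``counts`` of shape (len(theta), K+1). Returns (f, grad)."""
    a, d = x[0], x[1:]
    lp = gpcm_logprobs(a, d, theta)
    f = -float(np.sum(counts * lp))
    p = np.exp(lp)
    k = np.arange(d.shape[0] + 1, dtype=float)
    n_m = counts.sum(axis=1)
    e_m = p @ k
    obs_k = counts @ k
    g_a = -float(theta @ (obs_k - n_m * e_m))
    # P(K >= v | theta) and observed exceedance counts, v = 1..K
    p_ge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]
    c_ge = np.cumsum(counts[:, ::-1], axis=1)[:, ::-1][:, 1:]
    g_d = -(c_ge - n_m[:, None] * p_ge).sum(axis=0)
    return f, np.concatenate([[g_a], g_d])


def _maximize_item(x0, theta, counts):
    from scipy.optimize import minimize

    res = minimize(
        _neg_expected_item_ll, x0, args=(theta, counts), jac=True, method="BFGS",
        options={"gtol": 1e-9, "maxiter": 200},
    )
    return res.x


def _neg_expected_onepl_ll(x, theta, counts_by_item):
    """Shared-slope variant: x = (a, d_1..d_J). Returns (f, grad)."""
    a, ds = x[0], x[1:]
    f = 0.0
    g = np.zeros_like(x)
    for j, counts in enumerate(counts_by_item):
        fj, gj = _neg_expected_item_ll(np.array([a, ds[j]]), theta, counts)
        f += fj
        g[0] += gj[0]
        g[1 + j] = gj[1]
    return f, g


def fit_mml(
    resp: ResponseMatrix,
    model: str,
    impact=None,
    maxit: int = 500,
    tol: float = 1e-6,
    n_quad: int = 61,
) -> ModelFit:
    """Fit a 1PL, 2PL or GPCM by marginal ML (EM with Gauss-Hermite quadrature).

    Parameters
    ----------
    model : {"onepl", "twopl", "gpcm"}
    impact : array-like of group labels, optional
        Person grouping for multiple-group latent distributions; the first
        label encountered names the reference group (fixed N(0, 1)).
    maxit : maximum number of EM iterations (default 500); reaching it
        without meeting ``tol`` warns and sets ``converged=False``.
    tol : EM stops when the largest absolute parameter change is below this.
    """
    if model not in ("onepl", "twopl", "gpcm"):
        raise DataError(f"unknown MML model {model!r}")
    _check_categories(resp, model)
    _, group_names, group_idx = _group_setup(resp, impact)
    n_groups = len(group_names)
    u = resp.values
    j = resp.n_items
    quad = Quadrature.gauss_hermite(n_quad)
    log_w = np.log(quad.weights)

    # starting values: unit slopes, intercepts from marginal log-odds
    a = np.ones(j)
    d = []
    for jj in range(j):
        counts = np.bincount(u[:, jj], minlength=int(resp.n_categories[jj])).astype(float)
        counts = np.maximum(counts, 0.5)
        d.append(np.log(counts[1:] / counts[:-1]))
    means = np.zeros(n_groups)
    variances = np.ones(n_groups)

    model_name = f"{model}_mml"
    prev = _pack(model, a, d, means, variances)
    ll_path = []
    converged = False
    it = 0
    for it in range(1, maxit + 1):
        nodes_by_group = [means[g] + np.sqrt(variances[g]) * quad.nodes for g in range(n_groups)]
        tables = _item_logprob_tables(a, d, nodes_by_group)
        post, ll = _estep(u, group_idx, tables, log_w, n_groups)
        ll_path.append(float(ll.sum()))

        # pooled node locations and expected response counts per item
        theta_pool = np.concatenate(nodes_by_group)
        counts_by_item = []
        for jj in range(j):
            ncat = int(resp.n_categories[jj])
            blocks = []
            for g in range(n_groups):
                rows = group_idx == g
                onehot = np.eye(ncat)[u[rows, jj]]
                blocks.append(post[rows].T @ onehot)
            counts_by_item.append(np.concatenate(blocks, axis=0))

        if model == "onepl":
            x0 = np.concatenate([[a[0]], [dj[0] for dj in d]])
            x = _maximize_item_shared(x0, theta_pool, counts_by_item)
            a = np.full(j, x[0])
            d = [np.array([x[1 + jj]]) for jj in range(j)]
        else:
            for jj in range(j):
                x = _maximize_item(
                    np.concatenate([[a[jj]], d[jj]]), theta_pool, counts_by_item[jj]
                )
                a[jj] = x[0]
                d[jj] = x[1:]

        # impact M-step: posterior moments of the latent trait per group
        for g in range(1, n_groups):
            rows = group_idx == g
            w_g = post[rows]
            nodes = nodes_by_group[g]
            m1 = float((w_g @ nodes).mean())
            m2 = float((w_g @ (nodes - m1) ** 2).mean())
            means[g] = m1
            variances[g] = max(m2, 1e-6)

        params = _pack(model, a, d, means, variances)
        if np.max(np.abs(params - prev)) < tol:
            converged = True
            prev = params
            break
        prev = params

    if not converged:
        warnings.warn(
            f"EM did not converge in {maxit} iterations (tol={tol}); "
            "results may be inaccurate — increase maxit",
            ConvergenceWarning,
            stacklevel=2,
        )

    impact_obj = None
    if n_groups > 1:
        impact_obj = GroupImpact(
            group_index=group_idx,
            group_names=group_names,
            means=means.copy(),
            variances=variances.copy(),
        )
    labels = item_param_labels(model_name, resp.n_categories, resp.item_names)
    labels += impact_param_labels(group_names) if n_groups > 1 else []
    fit = ModelFit(
        model=model_name,
        params=prev,
        param_labels=labels,
        loglik=0.0,
        caselik=np.empty(0),
        converged=converged,
        n_iter=it,
        identification=(
            "latent trait N(0,1)" if n_groups == 1
            else f"reference group {group_names[0]!r} fixed at N(0,1)"
        ),
        n_categories=resp.n_categories.copy(),
        impact=impact_obj,
        quadrature=quad,
        loglik_path=np.asarray(ll_path),
    )
    cl = caselik_mml(fit, resp, fit.params)
    fit.caselik = cl
    fit.loglik = float(cl.sum())
    return fit


def _maximize_item_shared(x0, theta, counts_by_item):
    from scipy.optimize import minimize

    res = minimize(
        _neg_expected_onepl_ll, x0, args=(theta, counts_by_item), jac=True,
        method="BFGS", options={"gtol": 1e-9, "maxiter": 300},
    )
    return res.x


def _pack(model, a, d, means, variances):
    j = len(d)
    if model in ("onepl", "onepl_mml"):
        parts = [[a[0]], *[dj for dj in d]]
    else:
        parts = []
        for jj in range(j):
            parts.append([a[jj]])
            parts.append(d[jj])
    flat = np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])
    if means.shape[0] > 1:
        tail = np.empty(2 * (means.shape[0] - 1))
        tail[0::2] = means[1:]
        tail[1::2] = variances[1:]
        flat = np.concatenate([flat, tail])
    return flat


def posterior_weights(fit: ModelFit, resp: ResponseMatrix, params: np.ndarray | None = None):
    """E-step quantities at given parameters: (post, ll, nodes_by_group, group_idx)."""
    if fit.quadrature is None:
        raise ValueError("fit has no quadrature metadata; was it an MML fit?")
    if params is None:
        params = fit.params
    n_groups = fit.impact.n_groups if fit.impact is not None else 1
    group_idx = (
        fit.impact.group_index if fit.impact is not None
        else np.zeros(resp.n_persons, dtype=int)
    )
    a, d, means, variances = unpack_mml(fit.model, params, fit.n_categories, n_groups)
    quad = fit.quadrature
    nodes_by_group = [means[g] + np.sqrt(variances[g]) * quad.nodes for g in range(n_groups)]
    tables = _item_logprob_tables(a, d, nodes_by_group)
    post, ll = _estep(resp.values, group_idx, tables, np.log(quad.weights), n_groups)
    return post, ll, nodes_by_group, group_idx


def caselik_mml(fit: ModelFit, resp: ResponseMatrix, params: np.ndarray) -> np.ndarray:
    """Per-person marginal log-likelihood at ``params`` on the fit's grid."""
    _, ll, _, _ = posterior_weights(fit, resp, params)
    return ll
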