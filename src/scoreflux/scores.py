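"""Case-wise score contributions and their covariance standardization.

The score contribution of person i is the gradient of that person's
log-likelihood with respect to the free parameters, evaluated at the ML
estimate. At a converged fit the contributions sum to the zero vector
column-wise (the first-order condition), which anchors the fluctuation
process at 0 on both ends.

For MML fits the marginal derivative for the slope of item j is

    integral (u_ij - P_ij(theta)) * theta * P(theta | u_i, Psi) d theta

evaluated on the fit's quadrature grid; the intercept analogue drops the
theta factor, and for the GPCM the threshold derivative replaces the
residual by exceedance indicator minus exceedance probability. Under impact,
group mean/variance scores are posterior moments of the normal-density
derivatives, nonzero only for persons in that group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SingularCovarianceError
from .models import ModelFit, unpack_mml
from .mml import gpcm_logprobs, posterior_weights
from .rasch_cml import scores_rasch_cml_values
from .response import ResponseMatrix


@dataclass(frozen=True)
class ScoreMatrix:
    """N x P matrix of case-wise score contributions s(Psi_hat; u_i)."""

    values: np.ndarray
    param_labels: tuple
    fit_ref: str

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=list(self.param_labels)).to_csv(path, index=False)


def scores_rasch_cml(fit: ModelFit, resp: ResponseMatrix) -> ScoreMatrix:
    """Conditional score contributions of a CML Rasch fit (free difficulties)."""
    values = scores_rasch_cml_values(fit, resp)
    return ScoreMatrix(values, tuple(fit.param_labels), fit_ref=fit.model)


def scores_mml(fit: ModelFit, resp: ResponseMatrix) -> ScoreMatrix:
    """Marginal score contributions of a 1PL/2PL/GPCM fit.

    Columns follow ``fit.param_labels``; under impact the trailing columns are
    the non-reference group mean/variance scores.
    """
    if fit.model not in ("onepl_mml", "twopl_mml", "gpcm_mml"):
        raise TypeError(f"scores_mml expects an MML fit, got {fit.model!r}")
    post, _, nodes_by_group, group_idx = posterior_weights(fit, resp)
    n_groups = len(nodes_by_group)
    a, d, means, variances = unpack_mml(fit.model, fit.params, fit.n_categories, n_groups)
    u = resp.values
    n, j = u.shape

    slope_cols = np.zeros((n, j))
    int_cols = [np.zeros((n, len(d[jj]))) for jj in range(j)]
    for g in range(n_groups):
        rows = np.flatnonzero(group_idx == g)
        if rows.size == 0:
            continue
        nodes = nodes_by_group[g]
        w = post[rows]                      # (n_g, Q), rows sum to 1
        w_theta = w * nodes[None, :]
        for jj in range(j):
            p = np.exp(gpcm_logprobs(a[jj], d[jj], nodes))   # (Q, K+1)
            k = np.arange(p.shape[1], dtype=float)
            e_theta = p @ k                                   # E[K | theta]
            u_g = u[rows, jj]
            # slope: sum_q w_iq * theta_q * (u_ij - E[K|theta_q])
            slope_cols[rows, jj] = u_g * w_theta.sum(axis=1) - w_theta @ e_theta
            # thresholds v=1..K: indicator(u >= v) - P(K >= v | theta)
            p_ge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]  # (Q, K)
            ge = (u_g[:, None] >= np.arange(1, p.shape[1])[None, :]).astype(float)
            int_cols[jj][rows] = ge - w @ p_ge

    blocks = []
    if fit.model == "onepl_mml":
        blocks.append(slope_cols.sum(axis=1, keepdims=True))
        blocks.extend(int_cols)
    else:
        for jj in range(j):
            blocks.append(slope_cols[:, jj : jj + 1])
            blocks.append(int_cols[jj])

    if n_groups > 1:
        for g in range(1, n_groups):
            rows = group_idx == g
            nodes = nodes_by_group[g]
            mu, var = means[g], variances[g]
            s_mu = np.zeros((n, 1))
            s_var = np.zeros((n, 1))
            m1 = post[rows] @ nodes
            m2 = post[rows] @ (nodes - mu) ** 2
            s_mu[rows, 0] = (m1 - mu) / var
            s_var[rows, 0] = (m2 - var) / (2.0 * var**2)
            blocks.append(np.concatenate([s_mu, s_var], axis=1))

    values = np.concatenate(blocks, axis=1)
    return ScoreMatrix(values, tuple(fit.param_labels), fit_ref=fit.model)


def scores(fit: ModelFit, resp: ResponseMatrix) -> ScoreMatrix:
    """Dispatch to the CML or MML score computation for the given fit."""
    if fit.model == "rasch_cml":
        return scores_rasch_cml(fit, resp)
    return scores_mml(fit, resp)


def covariance_root(score_values, rtol: float = 1e-10):
    """Symmetric inverse square root of I_hat = S'S / N (outer product of
    gradients), via eigendecomposition.

    Raises
    ------
    SingularCovarianceError
        If any eigenvalue is below ``rtol`` times the largest — typically an
        identification problem; test a parameter subset instead.
    """
    s = score_values.values if isinstance(score_values, ScoreMatrix) else np.asarray(score_values)
    n = s.shape[0]
    info = (s.T @ s) / n
    eigval, eigvec = np.linalg.eigh(info)
    if eigval[-1] <= 0 or np.any(eigval < rtol * eigval[-1]):
        raise SingularCovarianceError(
            "score covariance matrix is numerically singular "
            f"(eigenvalue ratio {eigval[0] / max(eigval[-1], 1e-300):.2e}); "
            "consider testing a parameter subset (pars) with full rank"
        )
    return (eigvec * (1.0 / np.sqrt(eigval))) @ eigvec.T
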