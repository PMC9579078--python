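"""Fitted-model container and parameter-vector layout.

A fitted model is summarized by a flat parameter vector Psi of length P
(free parameters only) plus metadata describing the layout:

* ``rasch_cml``  — item difficulties ``b_2..b_J`` (item 1 fixed at 0).
* ``onepl_mml``  — shared slope ``a`` then intercepts ``d_1..d_J``.
* ``twopl_mml``  — item-major ``(a_j, d_j)`` pairs.
* ``gpcm_mml``   — item-major ``(a_j, d_j1..d_jK_j)`` blocks; intercepts enter
  cumulatively so a 2-category item collapses exactly to the 2PL.

Under impact (multiple-group latent distributions) the group means and
variances of the non-reference groups are appended as free parameters:
``(mu_g, sigma2_g)`` per group, reference group fixed at N(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .response import ResponseMatrix

MODELS = ("rasch_cml", "onepl_mml", "twopl_mml", "gpcm_mml")


@dataclass(frozen=True)
class Quadrature:
    """Gauss-Hermite grid for a standard-normal latent trait.

    ``nodes``/``weights`` are already transformed to N(0, 1); a group grid is
    ``mu_g + sigma_g * nodes`` with unchanged weights.
    """

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def gauss_hermite(cls, n: int = 61) -> "Quadrature":
        x, w = np.polynomial.hermite.hermgauss(n)
        return cls(nodes=np.sqrt(2.0) * x, weights=w / np.sqrt(np.pi))


@dataclass(frozen=True)
class GroupImpact:
    """Multiple-group latent-trait distributions (impact, not DIF)."""

    group_index: np.ndarray     # per-person integer group, 0 = reference
    group_names: tuple
    means: np.ndarray           # per group; means[0] == 0
    variances: np.ndarray       # per group; variances[0] == 1

    @property
    def n_groups(self) -> int:
        return len(self.group_names)


@dataclass
class ModelFit:
    """Estimation result: parameter vector, log-likelihood and provenance."""

    model: str
    params: np.ndarray
    param_labels: list
    loglik: float
    caselik: np.ndarray
    converged: bool
    n_iter: int
    identification: str
    n_categories: np.ndarray
    impact: GroupImpact | None = None
    quadrature: Quadrature | None = None
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_params(self) -> int:
        return self.params.shape[0]

    def item_param_indices(self) -> np.ndarray:
        """Indices of item parameters (excluding impact mean/variance columns)."""
        p_item = n_item_params(self.model, self.n_categories)
        return np.arange(p_item)


def n_item_params(model: str, n_categories: np.ndarray) -> int:
    n_categories = np.asarray(n_categories)
    j = n_categories.shape[0]
    if model == "rasch_cml":
        return j - 1
    if model == "onepl_mml":
        return 1 + j
    if model == "twopl_mml":
        return 2 * j
    if model == "gpcm_mml":
        return int(np.sum(n_categories))  # 1 slope + K_j intercepts per item
    raise DataError(f"unknown model {model!r}")


def item_param_labels(model: str, n_categories: np.ndarray, item_names) -> list:
    labels = []
    if model == "rasch_cml":
        return [f"{name}:b" for name in item_names[1:]]
    if model == "onepl_mml":
        return ["a"] + [f"{name}:d" for name in item_names]
    for name, ncat in zip(item_names, np.asarray(n_categories)):
        labels.append(f"{name}:a")
        if ncat == 2:
            labels.append(f"{name}:d")
        else:
            labels.extend(f"{name}:d{k}" for k in range(1, int(ncat)))
    return labels


def impact_param_labels(group_names) -> list:
    out = []
    for g in group_names[1:]:
        out.extend([f"group[{g}]:mean", f"group[{g}]:var"])
    return out


def unpack_mml(model: str, params: np.ndarray, n_categories: np.ndarray, n_groups: int):
    """Split a flat MML parameter vector into slopes, intercept blocks and
    group means/variances (reference group included, fixed at 0 / 1)."""
    params = np.asarray(params, dtype=float)
    n_categories = np.asarray(n_categories)
    j = n_categories.shape[0]
    p_item = n_item_params(model, n_categories)
    if model == "onepl_mml":
        a = np.full(j, params[0])
        d = [params[1 + k : 2 + k] for k in range(j)]
    elif model == "twopl_mml":
        a = params[0:p_item:2].copy()
        d = [params[2 * k + 1 : 2 * k + 2] for k in range(j)]
    elif model == "gpcm_mml":
        a = np.empty(j)
        d = []
        pos = 0
        for k in range(j):
            a[k] = params[pos]
            nk = int(n_categories[k]) - 1
            d.append(params[pos + 1 : pos + 1 + nk])
            pos += 1 + nk
    else:
        raise DataError(f"not an MML model: {model!r}")
    means = np.zeros(n_groups)
    variances = np.ones(n_groups)
    tail = params[p_item:]
    if n_groups > 1:
        if tail.shape[0] != 2 * (n_groups - 1):
            raise DataError("parameter vector does not match the number of impact groups")
        means[1:] = tail[0::2]
        variances[1:] = tail[1::2]
    return a, d, means, variances


def caselik(fit: ModelFit, resp: ResponseMatrix, params: np.ndarray | None = None) -> np.ndarray:
    """Per-person log-likelihood at ``fit.params`` or at an arbitrary ``params``.

    CML fits return the conditional per-person log-likelihood, MML fits the
    marginal one (quadrature-approximated on the fit's grid). Evaluating at
    perturbed parameters is what makes finite-difference validation of the
    analytic scores possible.
    """
    if resp.n_items != fit.n_categories.shape[0]:
        raise DataError("response matrix does not match the fitted model's items")
    if params is None:
        params = fit.params
    if fit.model == "rasch_cml":
        from .rasch_cml import caselik_rasch_cml

        return caselik_rasch_cml(params, resp)
    from .mml import caselik_mml

    return caselik_mml(fit, resp, params)
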