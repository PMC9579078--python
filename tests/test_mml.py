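"""Marginal ML estimation: item response functions and the EM algorithm."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

import scoreflux as sf


def test_irf_2pl_values():
    assert sf.irf_2pl(1.0, 0.0, 0.0) == 0.5
    assert sf.irf_2pl(0.0, 0.0, 3.7) == 0.5        # flat item
    # independent evaluation of exp(a*theta+d) / (1 + exp(a*theta+d))
    expected = np.exp(1.0) / (1.0 + np.exp(1.0))
    assert abs(sf.irf_2pl(2.0, -1.0, 1.0) - expected) < 1e-12
    assert sf.irf_2pl(1.0, 800.0, 1.0) == pytest.approx(1.0)  # overflow-safe


def test_gpcm_reduces_to_2pl_and_normalizes():
    a, d, theta = 1.3, np.array([0.4]), 0.7
    p = sf.gpcm_category_probs(a, d, theta)
    assert p[1] == pytest.approx(sf.irf_2pl(a, d[0], theta), abs=1e-14)
    rng = np.random.default_rng(3)
    for _ in range(10):
        p = sf.gpcm_category_probs(rng.normal(), rng.normal(size=4), rng.normal())
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)


def test_gpcm_probs_match_direct_arithmetic():
    a, d, theta = 1.0, np.array([0.5, -0.5]), 0.3
    num = np.array(
        [1.0, np.exp(a * theta + d[0]), np.exp(2 * a * theta + d[0] + d[1])]
    )
    np.testing.assert_allclose(
        sf.gpcm_category_probs(a, d, theta), num / num.sum(), rtol=1e-12
    )


def test_onepl_slopes_shared(twopl_data):
    _, resp, _, _ = twopl_data
    fit = sf.fit_mml(resp, "onepl")
    # one shared slope parameter by construction
    assert fit.param_labels[0] == "a"
    assert fit.params.size == 1 + resp.n_items
    s = sf.scores_mml(fit, resp)
    assert s.n_params == fit.params.size


def test_em_loglik_nondecreasing(twopl_fit, gpcm_fit):
    for fit in (twopl_fit, gpcm_fit):
        diffs = np.diff(fit.loglik_path)
        assert np.all(diffs >= -1e-6), f"EM log-likelihood decreased: {diffs.min()}"


def marginal_loglik_oracle(x, values, n_quad=61):
    """Independent 2PL marginal log-likelihood (own quadrature + expit)."""
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    nodes = np.sqrt(2.0) * gh_x
    logw = np.log(gh_w / np.sqrt(np.pi))
    a = x[0::2]
    d = x[1::2]
    p = expit(a[None, :] * nodes[:, None] + d[None, :])  # (Q, J)
    with np.errstate(divide="ignore"):
        lp = np.where(values[:, None, :] == 1, np.log(p)[None], np.log1p(-p)[None])
    return float(logsumexp(lp.sum(axis=2) + logw[None, :], axis=1).sum())


def test_em_matches_direct_marginal_optimizer():
    """EM solution agrees with an independent direct maximizer of the marginal
    likelihood (same data, same quadrature rule, no EM)."""
    design = sf.SimulationDesign(
        model="twopl",
        slopes=(0.9, 1.2, 1.5),
        intercepts=((-0.5,), (0.0,), (0.6,)),
        n_persons=400,
        seed=77,
    )
    resp, _, _ = sf.simulate_responses(design)
    fit = sf.fit_mml(resp, "twopl")

    res = minimize(
        lambda x: -marginal_loglik_oracle(x, resp.values),
        np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0]),
        method="BFGS",
        options={"gtol": 1e-8},
    )
    assert abs(-res.fun - fit.loglik) < 1e-4
    np.testing.assert_allclose(fit.params, res.x, atol=5e-3)


def test_twopl_intercept_recovery_improves_with_n():
    """RMSE of intercept estimates shrinks with sample size and is small at
    N=2000 (cross-checked against the direct-optimizer agreement above)."""
    truth_d = np.linspace(-1.5, 1.5, 5)
    rmses = {}
    for n in (250, 2000):
        design = sf.SimulationDesign(
            model="twopl",
            slopes=tuple(np.ones(5)),
            intercepts=tuple((x,) for x in truth_d),
            n_persons=n,
            seed=1234,
        )
        resp, _, _ = sf.simulate_responses(design)
        fit = sf.fit_mml(resp, "twopl")
        d_hat = fit.params[1::2]
        rmses[n] = float(np.sqrt(np.mean((d_hat - truth_d) ** 2)))
    assert rmses[2000] < rmses[250]
    assert rmses[2000] < 0.15


def test_impact_recovers_null_group_differences():
    """When both groups share N(0,1), the estimated non-reference mean/variance
    stay near 0/1 (within Monte-Carlo error at N=1500, J=10; group variances
    are weakly identified with few items, so the test uses a longer test)."""
    spec = sf.CovariateSpec("g", "unordered", levels=("u", "v"))
    design = sf.SimulationDesign(
        model="twopl",
        slopes=tuple(np.ones(10)),
        intercepts=tuple((x,) for x in np.linspace(-1.2, 1.2, 10)),
        n_persons=1500,
        seed=31,
        covariates=(spec,),
        impact={"covariate": "g", "means": (0.0, 0.0), "variances": (1.0, 1.0)},
    )
    resp, cov, _ = sf.simulate_responses(design)
    fit = sf.fit_mml(resp, "twopl", impact=cov["g"].to_numpy(), maxit=4000)
    assert fit.converged
    assert fit.impact.means[0] == 0.0 and fit.impact.variances[0] == 1.0
    assert abs(fit.impact.means[1]) < 0.15
    assert abs(fit.impact.variances[1] - 1.0) < 0.25


def test_unobserved_category_rejected():
    values = np.array([[0, 0], [1, 2], [2, 0], [0, 2], [2, 2], [1, 0]])
    resp = sf.ResponseMatrix.from_array(values, n_categories=[3, 3])
    with pytest.raises(sf.EstimationError, match="item02.*category 1"):
        sf.fit_mml(resp, "gpcm")


def test_single_impact_group_warns_and_ignores(twopl_data):
    _, resp, _, _ = twopl_data
    with pytest.warns(UserWarning, match="single level"):
        fit = sf.fit_mml(resp, "twopl", impact=np.repeat("only", resp.n_persons))
    assert fit.impact is None


def test_maxit_reached_warns_not_fails(twopl_data):
    _, resp, _, _ = twopl_data
    with pytest.warns(sf.ConvergenceWarning):
        fit = sf.fit_mml(resp, "twopl", maxit=2)
    assert not fit.converged
    assert fit.n_iter == 2
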