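import numpy as np
import pytest

import scoreflux as sf


@pytest.fixture(scope="session")
def rasch_data():
    """DIF-free Rasch data, N=200, J=5, with a continuous covariate."""
    design = sf.rasch_design(
        np.linspace(-1.0, 1.0, 5),
        n_persons=200,
        seed=20260101,
        covariates=(sf.CovariateSpec("age", "continuous", "uniform", (20.0, 60.0)),),
    )
    resp, cov, truth = sf.simulate_responses(design)
    return design, resp, cov, truth


@pytest.fixture(scope="session")
def rasch_fit(rasch_data):
    _, resp, _, _ = rasch_data
    return sf.fit_rasch_cml(resp)


@pytest.fixture(scope="session")
def twopl_data():
    design = sf.SimulationDesign(
        model="twopl",
        slopes=tuple(np.linspace(0.7, 1.6, 5)),
        intercepts=tuple((x,) for x in np.linspace(-1.2, 1.2, 5)),
        n_persons=200,
        seed=7121,
    )
    resp, cov, truth = sf.simulate_responses(design)
    return design, resp, cov, truth


@pytest.fixture(scope="session")
def twopl_fit(twopl_data):
    _, resp, _, _ = twopl_data
    return sf.fit_mml(resp, "twopl")


@pytest.fixture(scope="session")
def gpcm_data():
    rng = np.random.default_rng(515)
    intercepts = tuple(tuple(np.sort(rng.normal(0.0, 0.9, 3))[::-1]) for _ in range(5))
    design = sf.SimulationDesign(
        model="gpcm",
        slopes=(1.0, 0.8, 1.3, 1.0, 1.1),
        intercepts=intercepts,
        n_persons=200,
        seed=99,
    )
    resp, cov, truth = sf.simulate_responses(design)
    return design, resp, cov, truth


@pytest.fixture(scope="session")
def gpcm_fit(gpcm_data):
    _, resp, _, _ = gpcm_data
    return sf.fit_mml(resp, "gpcm")


def finite_difference_scores(fit, resp, step=1e-5):
    """Central finite differences of the per-person log-likelihood — the
    independent oracle for every analytic score computation."""
    out = np.empty((resp.n_persons, fit.params.size))
    for k in range(fit.params.size):
        up = fit.params.copy()
        dn = fit.params.copy()
        up[k] += step
        dn[k] -= step
        out[:, k] = (sf.caselik(fit, resp, up) - sf.caselik(fit, resp, dn)) / (2 * step)
    return out
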