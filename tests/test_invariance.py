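"""Orderings, the fluctuation process, and the four test statistics."""

import numpy as np
import pytest
from scipy import stats as spstats

import scoreflux as sf


def toy_scores(n=40, p=2, seed=1):
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((n, p))
    s -= s.mean(axis=0)  # mimic the MLE zero-sum identity
    return sf.ScoreMatrix(s, tuple(f"p{k}" for k in range(p)), "toy")


# --------------------------------------------------------------------------- #
# orderings
# --------------------------------------------------------------------------- #

def test_continuous_ordering_sorts_and_marks_changes():
    o = sf.build_ordering(np.array([3.0, 1.0, 2.0]), "continuous")
    np.testing.assert_array_equal(o.sort_index, [1, 2, 0])
    np.testing.assert_array_equal(o.boundaries, [1, 2])


def test_ties_are_aggregated():
    o = sf.build_ordering(np.array([1, 1, 2, 2]), "continuous")
    np.testing.assert_array_equal(o.boundaries, [2])


def test_ordered_levels_give_level_boundaries():
    rng = np.random.default_rng(0)
    area = rng.choice(["rural", "suburban", "urban"], size=2449)
    o = sf.build_ordering(area, "ordered", levels=["rural", "suburban", "urban"])
    assert o.boundaries.shape == (2,)  # 3 ordered levels -> 2 candidate cuts
    assert o.level_sizes.sum() == 2449


def test_ordering_input_errors():
    with pytest.raises(sf.UsageError, match="constant"):
        sf.build_ordering(np.ones(10), "continuous")
    with pytest.raises(sf.DataError, match="missing"):
        sf.build_ordering(np.array([1.0, np.nan, 2.0]), "continuous")
    with pytest.raises(sf.UsageError, match="constant"):
        sf.build_ordering(np.repeat("a", 5), "unordered")


# --------------------------------------------------------------------------- #
# the process
# --------------------------------------------------------------------------- #

def test_process_is_anchored_at_zero():
    sm = toy_scores()
    o = sf.build_ordering(np.random.default_rng(2).normal(size=40), "continuous")
    pr = sf.cumulative_process(sm, o)
    np.testing.assert_allclose(pr.cumsum[0], 0.0, atol=1e-12)
    np.testing.assert_allclose(pr.cumsum[-1], 0.0, atol=1e-6)


def test_single_par_process_is_univariate_cusum():
    sm = toy_scores()
    cov = np.random.default_rng(3).normal(size=40)
    o = sf.build_ordering(cov, "continuous")
    pr = sf.cumulative_process(sm, o, pars=[1])
    col = sm.values[o.sort_index, 1]
    sd = np.sqrt(np.mean(sm.values[:, 1] ** 2))
    np.testing.assert_allclose(
        pr.cumsum[1:, 0], np.cumsum(col) / (sd * np.sqrt(40)), atol=1e-10
    )


# --------------------------------------------------------------------------- #
# statistics vs their defining functionals
# --------------------------------------------------------------------------- #

def brute_force_sup_lm(s, order, boundaries, n):
    root = sf.covariance_root(s)
    ss = s[order]
    best, where = -np.inf, None
    for i in boundaries:
        t = i / n
        b = (root @ ss[:i].sum(axis=0)) / np.sqrt(n)
        v = float(b @ b) / (t * (1 - t))
        if v > best:
            best, where = v, i
    return best, where


def test_maxlm_equals_brute_force_enumeration():
    for seed in (1, 2, 3):
        sm = toy_scores(n=50, p=3, seed=seed)
        cov = np.random.default_rng(seed + 10).normal(size=50)
        o = sf.build_ordering(cov, "continuous")
        pr = sf.cumulative_process(sm, o, trim=(0.1, 0.9))
        r = sf.stat_maxlm(pr, reps=500, seed=0)
        lo, hi = int(np.floor(50 * 0.1)), int(np.ceil(50 * 0.9))
        admissible = [i for i in o.boundaries if lo <= i <= hi]
        expected, where = brute_force_sup_lm(sm.values, o.sort_index, admissible, 50)
        assert abs(r.statistic - expected) < 1e-10
        assert r.location == where


def test_maxlm_invariant_to_covariate_reversal():
    sm = toy_scores(n=60, p=2, seed=9)
    cov = np.random.default_rng(11).normal(size=60)
    o1 = sf.build_ordering(cov, "continuous")
    o2 = sf.build_ordering(-cov, "continuous")
    r1 = sf.stat_maxlm(sf.cumulative_process(sm, o1), reps=200, seed=0)
    r2 = sf.stat_maxlm(sf.cumulative_process(sm, o2), reps=200, seed=0)
    assert abs(r1.statistic - r2.statistic) < 1e-10


def test_maxlm_needs_admissible_boundary():
    sm = toy_scores(n=20, p=1, seed=4)
    cov = np.concatenate([np.zeros(10), np.ones(10)])  # only split at t=0.5
    o = sf.build_ordering(cov, "continuous")
    pr = sf.cumulative_process(sm, o, trim=(0.6, 0.9))
    with pytest.raises(sf.UsageError, match="trim"):
        sf.stat_maxlm(pr, reps=100, seed=0)


def test_lmuo_matches_direct_quadratic_form_and_label_permutation():
    sm = toy_scores(n=45, p=3, seed=5)
    rng = np.random.default_rng(6)
    g = rng.choice(["x", "y", "z"], size=45)
    o = sf.build_ordering(g, "unordered")
    r = sf.stat_lmuo(sm, o)
    root = sf.covariance_root(sm.values)
    expected = 0.0
    for lev in ("x", "y", "z"):
        w = root @ sm.values[g == lev].sum(axis=0) / np.sqrt(45)
        expected += float(w @ w) * 45 / (g == lev).sum()
    assert abs(r.statistic - expected) < 1e-10
    assert r.pvalue_method == "chisq(df=6)"  # P*(m-1) = 3*2
    # permuting level labels changes nothing
    relabel = {"x": "z", "y": "x", "z": "y"}
    g2 = np.array([relabel[v] for v in g])
    r2 = sf.stat_lmuo(sm, sf.build_ordering(g2, "unordered"))
    assert abs(r.statistic - r2.statistic) < 1e-10


def test_maxlmo_two_levels_reduces_to_single_cut_chisq():
    """With m=2 the statistic is the single-cut LM value and its chi-square_P
    tail probability agrees with the Monte-Carlo p-value within simulation
    error."""
    sm = toy_scores(n=80, p=2, seed=12)
    g = np.repeat(["lo", "hi"], 40)
    o = sf.build_ordering(g, "ordered", levels=["lo", "hi"])
    r = sf.stat_maxlmo(sm, o, reps=40_000, seed=2)
    expected, _ = brute_force_sup_lm(sm.values, o.sort_index, [40], 80)
    assert abs(r.statistic - expected) < 1e-10
    p_chisq = float(spstats.chi2.sf(r.statistic, 2))
    se = np.sqrt(p_chisq * (1 - p_chisq) / 40_000)
    assert abs(r.p_value - p_chisq) < 4 * se + 1e-3


def test_maxlmo_invariant_to_level_order_reversal():
    sm = toy_scores(n=60, p=2, seed=13)
    rng = np.random.default_rng(14)
    g = rng.choice(["a", "b", "c"], size=60)
    r1 = sf.stat_maxlmo(sm, sf.build_ordering(g, "ordered", levels=["a", "b", "c"]),
                        reps=200, seed=0)
    r2 = sf.stat_maxlmo(sm, sf.build_ordering(g, "ordered", levels=["c", "b", "a"]),
                        reps=200, seed=0)
    assert abs(r1.statistic - r2.statistic) < 1e-10


def test_dm_degenerate_process():
    pr = sf.ScoreProcess(np.zeros((11, 2)), np.arange(1, 10), "continuous")
    r = sf.stat_dm(pr)
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_dm_equals_max_abs_entry():
    sm = toy_scores(n=50, p=3, seed=21)
    cov = np.random.default_rng(22).normal(size=50)
    pr = sf.cumulative_process(sm, sf.build_ordering(cov, "continuous"))
    r = sf.stat_dm(pr)
    assert abs(r.statistic - np.abs(pr.cumsum).max()) < 1e-12


# --------------------------------------------------------------------------- #
# driver and pairing rules
# --------------------------------------------------------------------------- #

def test_run_test_pairing_rules(rasch_fit, rasch_data):
    _, resp, cov, _ = rasch_data
    age = cov["age"].to_numpy()
    with pytest.raises(sf.UsageError, match="LMuo"):
        sf.run_test(rasch_fit, resp, age, "continuous", "LMuo")
    with pytest.raises(sf.UsageError, match="maxLMo"):
        sf.run_test(rasch_fit, resp, age, "continuous", "maxLMo")
    g = np.where(age > np.median(age), "a", "b")
    with pytest.raises(sf.UsageError):
        sf.run_test(rasch_fit, resp, g, "unordered", "maxLM")


def test_run_test_full_provenance(rasch_fit, rasch_data):
    _, resp, cov, _ = rasch_data
    r = sf.run_test(
        rasch_fit, resp, cov["age"].to_numpy(), "continuous", "maxLM",
        reps=2000, seed=5,
    )
    assert r.functional == "maxLM"
    assert r.n_obs == resp.n_persons
    assert r.n_pars == resp.n_items - 1
    assert "reps=2000" in r.pvalue_method and "seed=5" in r.pvalue_method
    assert 0.0 <= r.p_value <= 1.0


def test_run_test_subset_restricts_parameters(gpcm_fit, gpcm_data):
    """Testing only item 1's parameters (one slope + K thresholds)."""
    _, resp, _, _ = gpcm_data
    rng = np.random.default_rng(17)
    area = rng.choice(["rural", "suburban", "urban"], size=resp.n_persons)
    r = sf.run_test(
        gpcm_fit, resp, area, "ordered", "maxLMo",
        pars=range(0, 4), levels=["rural", "suburban", "urban"], reps=2000, seed=1,
    )
    assert r.n_pars == 4
    assert tuple(r.pars) == (0, 1, 2, 3)


def test_two_group_lmuo_null_distribution_is_chisq():
    """Over repeated DIF-free datasets (fixed generating parameters, refit and
    score recomputation each time), the two-group LMuo statistic follows
    chi-square with P degrees of freedom."""
    n_reps = 2000
    stats = np.empty(n_reps)
    master = np.random.SeedSequence(606).spawn(n_reps)
    base = sf.rasch_design(
        np.linspace(-1, 1, 4),
        n_persons=400,
        seed=0,
        covariates=(sf.CovariateSpec("g", "unordered", levels=("a", "b")),),
    )
    from dataclasses import replace

    for i, child in enumerate(master):
        d = replace(base, seed=int(child.generate_state(1)[0] % 2**31))
        resp, cov, _ = sf.simulate_responses(d)
        fit = sf.fit_rasch_cml(resp)
        sm = sf.scores(fit, resp)
        o = sf.build_ordering(cov["g"].to_numpy(), "unordered")
        stats[i] = sf.stat_lmuo(sm, o).statistic
    ks = spstats.kstest(stats, spstats.chi2(3).cdf)
    assert ks.pvalue > 0.01
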