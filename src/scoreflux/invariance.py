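"""Score-based tests of measurement invariance.

Respondents are ordered by a person covariate; the standardized cumulative
score process

    B(t, Psi_hat) = I_hat^{-1/2} N^{-1/2} sum_{i <= floor(N t)} s(Psi_hat; u_(i))

converges component-wise to a Brownian bridge under the null hypothesis of
parameter invariance. Four functionals summarize departures:

* ``DM``      — double maximum, max over persons and parameters of |B|;
                analytic p-value from bridge boundary-crossing probabilities.
* ``maxLM``   — maximally selected LM statistic over candidate split points
                of a continuous covariate, sup of ||B(t)||^2 / (t (1 - t));
                Monte-Carlo p-value.
* ``maxLMo``  — the same functional restricted to the level boundaries of an
                ordered covariate; Monte-Carlo p-value on the observed cut
                proportions.
* ``LMuo``    — unordered LM statistic aggregating within-level score sums;
                chi-square with P * (m - 1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .errors import DataError, UsageError
from .models import ModelFit
from .response import ResponseMatrix
from .scores import ScoreMatrix, covariance_root, scores

FUNCTIONALS = ("DM", "maxLM", "LMuo", "maxLMo")


# --------------------------------------------------------------------------- #
# covariate orderings
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class CovariateOrdering:
    """A person ordering induced by a covariate.

    ``boundaries`` holds, for continuous/ordered kinds, the 1-based counts of
    persons strictly before each change of the sorted covariate value (ties
    are aggregated, so the process is only evaluated between distinct values).
    """

    kind: str
    sort_index: np.ndarray
    boundaries: np.ndarray
    levels: tuple = field(default=())
    level_sizes: np.ndarray = field(default=None)

    @property
    def n_obs(self) -> int:
        return self.sort_index.shape[0]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def build_ordering(covariate, kind: str, levels=None) -> CovariateOrdering:
    """Sort persons by a covariate and locate the candidate split points.

    Parameters
    ----------
    covariate : array-like of length N
    kind : {"continuous", "ordered", "unordered"}
    levels : explicit level order for ordered/unordered categorical
        covariates; inferred (sorted unique) if omitted.
    """
    cov = np.asarray(covariate)
    if kind not in ("continuous", "ordered", "unordered"):
        raise UsageError(f"unknown covariate kind {kind!r}")
    if cov.ndim != 1 or cov.shape[0] < 2:
        raise DataError("covariate must be a vector with at least 2 entries")
    if cov.dtype.kind in "fc" and not np.all(np.isfinite(cov)):
        raise DataError("covariate contains missing/non-finite values")
    if cov.dtype.kind == "O" and any(v is None or v != v for v in cov):
        raise DataError("covariate contains missing values")
    if np.unique(cov).shape[0] < 2:
        raise UsageError("covariate is constant: there is no invariance question to test")

    if kind == "continuous":
        if cov.dtype.kind not in "fiu":
            raise DataError("a continuous covariate must be numeric")
        order = np.argsort(cov, kind="stable")
        svals = cov[order]
        change = np.flatnonzero(svals[1:] != svals[:-1]) + 1
        return CovariateOrdering(kind, order, change.astype(int))

    if levels is None:
        levels = np.unique(cov).tolist()
    levels = list(levels)
    observed = set(np.unique(cov).tolist())
    if not observed.issubset(set(levels)):
        raise DataError(f"covariate values {sorted(observed - set(levels))} not in declared levels")
    rank = {lev: i for i, lev in enumerate(levels)}
    codes = np.array([rank[v] for v in cov.tolist()])
    sizes = np.bincount(codes, minlength=len(levels))
    keep = sizes > 0
    levels = [lev for lev, k in zip(levels, keep) if k]
    codes = np.searchsorted(np.flatnonzero(keep), codes)
    sizes = sizes[keep]
    if len(levels) < 2:
        raise UsageError("categorical covariate needs at least 2 nonempty levels")
    order = np.argsort(codes, kind="stable")
    boundaries = np.cumsum(sizes)[:-1]
    return CovariateOrdering(
        kind, order, boundaries.astype(int), tuple(levels), sizes.astype(int)
    )


# --------------------------------------------------------------------------- #
# the fluctuation process
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ScoreProcess:
    """Standardized cumulative score process on the grid i/N, i = 0..N."""

    cumsum: np.ndarray          # (N+1, P); rows 0 and N are zero at the MLE
    boundaries: np.ndarray      # admissible split indices (tie-aware)
    kind: str
    trim: tuple = (0.1, 0.9)
    pars: tuple = ()

    @property
    def n_obs(self) -> int:
        return self.cumsum.shape[0] - 1

    @property
    def n_pars(self) -> int:
        return self.cumsum.shape[1]


def cumulative_process(
    score_matrix: ScoreMatrix,
    ordering: CovariateOrdering,
    pars=None,
    trim: tuple = (0.1, 0.9),
) -> ScoreProcess:
    """Standardize the selected score columns and accumulate in covariate order.

    ``pars`` selects parameter columns before standardization, so the
    covariance estimate I_hat refers to the tested subset only.
    """
    if ordering.n_obs != score_matrix.n_obs:
        raise DataError("ordering and score matrix disagree on N")
    s = score_matrix.values
    pars = tuple(range(s.shape[1])) if pars is None else tuple(int(p) for p in pars)
    if any(p < 0 or p >= s.shape[1] for p in pars):
        raise DataError(f"pars out of range 0..{s.shape[1] - 1}")
    s = s[:, pars]
    root = covariance_root(s)
    n = s.shape[0]
    sorted_s = s[ordering.sort_index]
    b = np.vstack([np.zeros((1, len(pars))), np.cumsum(sorted_s, axis=0)])
    b = (b @ root) / np.sqrt(n)
    return ScoreProcess(b, ordering.boundaries.copy(), ordering.kind, tuple(trim), pars)


# --------------------------------------------------------------------------- #
# test results and statistics
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class TestResult:
    functional: str
    statistic: float
    p_value: float
    pars: tuple
    n_obs: int
    n_pars: int
    pvalue_method: str
    location: object = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")

    def summary(self) -> str:
        loc = f", at {self.location}" if self.location is not None else ""
        return (
            f"{self.functional} statistic = {self.statistic:.4g}, "
            f"p-value = {self.p_value:.4g} ({self.pvalue_method}{loc}; "
            f"N = {self.n_obs}, {self.n_pars} parameters)"
        )


def _bridge_crossing_prob(c: float, terms: int = 100) -> float:
    """P(sup |Brownian bridge| > c) via the alternating exponential series."""
    if c <= 0.05:
        return 1.0
    k = np.arange(1, terms + 1, dtype=float)
    p = 2.0 * np.sum((-1.0) ** (k + 1) * np.exp(-2.0 * k**2 * c**2))
    return float(min(max(p, 0.0), 1.0))


def stat_dm(process: ScoreProcess) -> TestResult:
    """Double-maximum statistic max_{i,p} |B(i/N)_p| with analytic p-value.

    Per component the limit is the sup of a |Brownian bridge|; the components
    are asymptotically independent after standardization, so the combined
    p-value is 1 - (1 - p_1)^P. Because the statistic is the maximum over the
    N-point grid rather than the continuous-time sup, the series is evaluated
    at the continuity-corrected level c + 0.5826 / sqrt(N) (the
    Broadie-Glasserman barrier shift); the uncorrected series would be
    conservative for moderate N.
    """
    if process.kind == "unordered":
        raise UsageError("DM requires a continuous or ordered covariate")
    b = np.abs(process.cumsum)
    stat = float(b.max())
    i, p = np.unravel_index(int(b.argmax()), b.shape)
    if stat == 0.0:
        pval = 1.0
    else:
        p1 = _bridge_crossing_prob(stat + 0.5826 / np.sqrt(process.n_obs))
        pval = float(min(max(1.0 - (1.0 - p1) ** process.n_pars, 0.0), 1.0))
    return TestResult(
        "DM", stat, pval, process.pars, process.n_obs, process.n_pars,
        "analytic (boundary-crossing series, grid-corrected)", location=int(i),
    )


_NULL_CACHE: dict = {}


def _sup_lm_null_sample(t_grid: tuple, n_pars: int, reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo sample of sup_t ||BB(t)||^2 / (t(1-t)) of a P-dimensional
    Brownian bridge evaluated on a fixed time grid. Cached: calibration
    studies with a common grid reuse one null sample (a fixed critical value)."""
    key = (t_grid, n_pars, reps, seed)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    ts = np.asarray(t_grid)
    dt = np.diff(np.concatenate([[0.0], ts, [1.0]]))
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    weight = 1.0 / (ts * (1.0 - ts))
    chunk = max(1, int(2_000_000 // max(1, (ts.size + 1) * n_pars)))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        incr = rng.standard_normal((m, ts.size + 1, n_pars)) * np.sqrt(dt)[None, :, None]
        w = np.cumsum(incr, axis=1)
        bridge = w[:, :-1, :] - ts[None, :, None] * w[:, -1:, :]
        out[done : done + m] = ((bridge**2).sum(axis=2) * weight[None, :]).max(axis=1)
        done += m
    if len(_NULL_CACHE) > 32:
        _NULL_CACHE.clear()
    _NULL_CACHE[key] = out
    return out


def _sup_lm_over(process: ScoreProcess, idx: np.ndarray):
    n = process.n_obs
    ts = idx / n
    vals = (process.cumsum[idx] ** 2).sum(axis=1) / (ts * (1.0 - ts))
    k = int(vals.argmax())
    return float(vals[k]), int(idx[k]), ts


def stat_maxlm(process: ScoreProcess, reps: int = 50_000, seed: int = 0) -> TestResult:
    """Maximally selected LM statistic over admissible split points of a
    continuous covariate, with a seeded Monte-Carlo p-value."""
    if process.kind not in ("continuous", "ordered"):
        raise UsageError("maxLM requires a continuous (or rank-ordered) covariate")
    n = process.n_obs
    lo = int(np.floor(n * process.trim[0]))
    hi = int(np.ceil(n * process.trim[1]))
    idx = process.boundaries[(process.boundaries >= lo) & (process.boundaries <= hi)]
    if idx.size == 0:
        raise UsageError(
            f"no admissible split point inside the trim window {process.trim}; "
            "widen the window or check for heavy ties"
        )
    stat, loc, ts = _sup_lm_over(process, idx)
    null = _sup_lm_null_sample(tuple(np.round(ts, 12)), process.n_pars, reps, seed)
    pval = float(np.mean(null >= stat))
    return TestResult(
        "maxLM", stat, pval, process.pars, n, process.n_pars,
        f"montecarlo(reps={reps}, seed={seed})", location=loc,
    )


def stat_lmuo(score_matrix: ScoreMatrix, ordering: CovariateOrdering, pars=None) -> TestResult:
    """Unordered LM statistic: sum over levels of the squared standardized
    within-level score sum, scaled by N / n_l; chi-square_{P (m-1)} p-value."""
    if ordering.kind != "unordered":
        raise UsageError("LMuo requires an unordered categorical covariate")
    s = score_matrix.values
    pars = tuple(range(s.shape[1])) if pars is None else tuple(int(p) for p in pars)
    s = s[:, pars]
    root = covariance_root(s)
    n = s.shape[0]
    codes = np.empty(n, dtype=int)
    codes[ordering.sort_index] = np.repeat(
        np.arange(ordering.n_levels), ordering.level_sizes
    )
    stat = 0.0
    for lev in range(ordering.n_levels):
        rows = codes == lev
        w = root @ s[rows].sum(axis=0) / np.sqrt(n)
        stat += float(w @ w) * n / rows.sum()
    df = len(pars) * (ordering.n_levels - 1)
    pval = float(spstats.chi2.sf(stat, df))
    return TestResult(
        "LMuo", float(stat), pval, pars, n, len(pars), f"chisq(df={df})",
    )


def stat_maxlmo(
    score_matrix: ScoreMatrix,
    ordering: CovariateOrdering,
    pars=None,
    reps: int = 50_000,
    seed: int = 0,
) -> TestResult:
    """Maximally selected LM statistic across the level boundaries of an
    ordered covariate, with a Monte-Carlo p-value at the observed cut
    proportions."""
    if ordering.kind != "ordered":
        raise UsageError("maxLMo requires an ordered categorical covariate")
    process = cumulative_process(score_matrix, ordering, pars=pars, trim=(0.0, 1.0))
    stat, loc, ts = _sup_lm_over(process, process.boundaries)
    null = _sup_lm_null_sample(tuple(np.round(ts, 12)), process.n_pars, reps, seed)
    pval = float(np.mean(null >= stat))
    level = ordering.levels[int(np.searchsorted(process.boundaries, loc))]
    return TestResult(
        "maxLMo", stat, pval, process.pars, process.n_obs, process.n_pars,
        f"montecarlo(reps={reps}, seed={seed})", location=level,
    )


# --------------------------------------------------------------------------- #
# one-call driver
# --------------------------------------------------------------------------- #

_PAIRING = {
    "DM": ("continuous", "ordered"),
    "maxLM": ("continuous", "ordered"),
    "maxLMo": ("ordered",),
    "LMuo": ("unordered",),
}


def run_test(
    fit: ModelFit,
    resp: ResponseMatrix,
    covariate,
    kind: str,
    functional: str,
    pars=None,
    levels=None,
    trim: tuple = (0.1, 0.9),
    reps: int = 50_000,
    seed: int = 0,
    include_impact_pars: bool = False,
) -> TestResult:
    """Fit-to-p-value driver: scores, ordering, statistic, p-value.

    ``pars`` defaults to all item parameters; impact (group mean/variance)
    columns are excluded unless ``include_impact_pars`` is set or they are
    named explicitly.
    """
    if functional not in FUNCTIONALS:
        raise UsageError(f"unknown functional {functional!r}; choose from {FUNCTIONALS}")
    if kind not in _PAIRING[functional]:
        raise UsageError(
            f"functional {functional} cannot be used with a {kind} covariate; "
            f"it expects {' or '.join(_PAIRING[functional])}. Use LMuo for "
            "unordered, maxLMo for ordered, maxLM/DM for continuous covariates."
        )
    cov = np.asarray(covariate)
    if cov.shape[0] != resp.n_persons:
        raise DataError("covariate length does not match the number of persons")
    sm = scores(fit, resp)
    if pars is None:
        pars = tuple(fit.item_param_indices()) if not include_impact_pars else tuple(
            range(sm.n_params)
        )
    ordering = build_ordering(cov, "continuous" if kind == "continuous" else kind, levels)
    if functional == "LMuo":
        return stat_lmuo(sm, ordering, pars=pars)
    if functional == "maxLMo":
        return stat_maxlmo(sm, ordering, pars=pars, reps=reps, seed=seed)
    process = cumulative_process(sm, ordering, pars=pars, trim=trim)
    if functional == "DM":
        return stat_dm(process)
    return stat_maxlm(process, reps=reps, seed=seed)
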