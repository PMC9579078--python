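"""Synthetic response data with known IRT structure, impact and DIF.

The generator draws a latent trait per person (optionally group-specific:
impact), modifies item parameters per person according to the declared DIF
effects, and samples responses from the model's category probabilities. Two
DIF effect forms are supported: a group shift (the affected subsample —
"second half" for numeric covariates, chosen levels for categorical ones —
gets the parameter shifted by ``size``) and a linear-in-covariate drift
(``size`` times the z-standardized covariate).

Every design carries a mandatory seed; replication streams in
``rejection_rate_study`` are spawned from it so studies are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, StudyError
from .invariance import run_test
from .mml import fit_mml
from .rasch_cml import fit_rasch_cml
from .response import ResponseMatrix


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated person covariate."""

    name: str
    kind: str                        # continuous | ordered | unordered
    distribution: str = "normal"     # continuous: normal | uniform
    params: tuple = (0.0, 1.0)       # (mean, sd) or (low, high)
    levels: tuple = ()               # categorical level labels
    probs: tuple = ()                # categorical level probabilities

    def __post_init__(self):
        if self.kind not in ("continuous", "ordered", "unordered"):
            raise ConfigError(f"covariate {self.name}: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            if self.distribution not in ("normal", "uniform"):
                raise ConfigError(f"covariate {self.name}: unknown distribution")
        else:
            if len(self.levels) < 2:
                raise ConfigError(f"covariate {self.name}: need >= 2 levels")
            probs = self.probs if self.probs else tuple([1 / len(self.levels)] * len(self.levels))
            object.__setattr__(self, "probs", tuple(probs))
            if len(self.probs) != len(self.levels) or abs(sum(self.probs) - 1) > 1e-8 or min(
                self.probs
            ) <= 0:
                raise ConfigError(f"covariate {self.name}: invalid level probabilities")


@dataclass(frozen=True)
class DifSpec:
    """One DIF effect: which item parameter drifts along which covariate."""

    item: int                       # 0-based item index
    param: str                      # slope | intercept | difficulty | threshold
    covariate: str
    form: str = "shift"             # shift | linear
    size: float = 0.0
    threshold_index: int = 0        # 0-based, for param == "threshold"
    affected_levels: tuple = ()     # categorical shift; default: all but first level

    def __post_init__(self):
        if self.param not in ("slope", "intercept", "difficulty", "threshold"):
            raise ConfigError(f"unknown DIF parameter kind {self.param!r}")
        if self.form not in ("shift", "linear"):
            raise ConfigError(f"unknown DIF form {self.form!r}")


@dataclass(frozen=True)
class SimulationDesign:
    model: str                      # rasch | twopl | gpcm
    slopes: tuple
    intercepts: tuple               # per item: tuple of K_j intercepts
    n_persons: int
    seed: int
    covariates: tuple = ()
    impact: dict | None = None      # {"covariate": name, "means": ..., "variances": ...}
    dif: tuple = ()

    def __post_init__(self):
        if self.model not in ("rasch", "twopl", "gpcm"):
            raise ConfigError(f"unknown simulation model {self.model!r}")
        if self.seed is None:
            raise ConfigError("a seed is mandatory in a simulation design")
        slopes = tuple(float(a) for a in self.slopes)
        intercepts = tuple(tuple(float(x) for x in np.atleast_1d(d)) for d in self.intercepts)
        if len(slopes) != len(intercepts):
            raise ConfigError("slopes and intercepts disagree on the number of items")
        if self.model == "rasch" and any(a != 1.0 for a in slopes):
            raise ConfigError("the Rasch model has unit slopes")
        if self.model in ("rasch", "twopl") and any(len(d) != 1 for d in intercepts):
            raise ConfigError("dichotomous models take a single intercept per item")
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "intercepts", intercepts)
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate covariate names")
        for eff in self.dif:
            if not 0 <= eff.item < len(slopes):
                raise ConfigError(f"DIF effect targets unknown item {eff.item}")
            if eff.covariate not in names:
                raise ConfigError(f"DIF effect references unknown covariate {eff.covariate!r}")
            if eff.param == "threshold" and not (
                0 <= eff.threshold_index < len(intercepts[eff.item])
            ):
                raise ConfigError("DIF threshold index out of range")
        if self.impact is not None:
            cov = next((c for c in self.covariates if c.name == self.impact["covariate"]), None)
            if cov is None or cov.kind == "continuous":
                raise ConfigError("impact requires a categorical covariate of the design")
            if len(self.impact["means"]) != len(cov.levels) or len(
                self.impact["variances"]
            ) != len(cov.levels):
                raise ConfigError("impact means/variances must match the covariate's levels")

    @property
    def n_items(self) -> int:
        return len(self.slopes)

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([len(d) + 1 for d in self.intercepts])


def rasch_design(
    difficulties, n_persons: int, seed: int, covariates=(), impact=None, dif=()
) -> SimulationDesign:
    """Convenience constructor: Rasch design from difficulties (d_j = -b_j)."""
    difficulties = np.asarray(difficulties, dtype=float)
    return SimulationDesign(
        model="rasch",
        slopes=tuple(np.ones(difficulties.shape[0])),
        intercepts=tuple((-b,) for b in difficulties),
        n_persons=n_persons,
        seed=seed,
        covariates=tuple(covariates),
        impact=impact,
        dif=tuple(dif),
    )


def _draw_covariates(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    n = design.n_persons
    for spec in design.covariates:
        if spec.kind == "continuous":
            lo, hi = spec.params
            if spec.distribution == "normal":
                cols[spec.name] = rng.normal(lo, hi, size=n)
            else:
                cols[spec.name] = rng.uniform(lo, hi, size=n)
        else:
            idx = rng.choice(len(spec.levels), size=n, p=np.asarray(spec.probs))
            cols[spec.name] = np.asarray(spec.levels, dtype=object)[idx]
    return pd.DataFrame(cols if cols else {}, index=pd.RangeIndex(n))


def _affected_mask(spec: DifSpec, values: np.ndarray, cov_spec: CovariateSpec) -> np.ndarray:
    if cov_spec.kind == "continuous":
        return values > np.median(values)
    levels = spec.affected_levels if spec.affected_levels else cov_spec.levels[1:]
    return np.isin(values, np.asarray(levels, dtype=object))


def person_item_params(design: SimulationDesign, covariates: pd.DataFrame):
    """Per-person item parameters implied by the design and realized covariates.

    Returns (slopes, intercepts): arrays of shape (N, J) and (N, J, K_max)
    (unused threshold slots hold NaN). This is the reconstruction the truth
    record promises: DIF effects are deterministic functions of covariates.
    """
    n, j = design.n_persons, design.n_items
    kmax = int((design.n_categories - 1).max())
    a = np.tile(np.asarray(design.slopes), (n, 1))
    d = np.full((n, j, kmax), np.nan)
    for jj in range(j):
        d[:, jj, : len(design.intercepts[jj])] = design.intercepts[jj]
    spec_by_name = {c.name: c for c in design.covariates}
    for eff in design.dif:
        values = covariates[eff.covariate].to_numpy()
        cov_spec = spec_by_name[eff.covariate]
        if eff.form == "shift":
            delta = eff.size * _affected_mask(eff, values, cov_spec).astype(float)
        else:
            if cov_spec.kind != "continuous":
                raise ConfigError("linear DIF requires a continuous covariate")
            z = (values - values.mean()) / values.std()
            delta = eff.size * z
        if eff.param == "slope":
            a[:, eff.item] += delta
        elif eff.param == "intercept":
            d[:, eff.item, 0] += delta
        elif eff.param == "difficulty":
            d[:, eff.item, 0] -= delta   # difficulty is the negative intercept
        else:
            d[:, eff.item, eff.threshold_index] += delta
    return a, d


def simulate_responses(design: SimulationDesign):
    """Draw (responses, covariate table, truth record) from a design."""
    rng = np.random.default_rng(design.seed)
    n, j = design.n_persons, design.n_items
    cov = _draw_covariates(design, rng)

    means = np.zeros(n)
    sds = np.ones(n)
    if design.impact is not None:
        spec = next(c for c in design.covariates if c.name == design.impact["covariate"])
        codes = pd.Categorical(
            cov[spec.name], categories=list(spec.levels)
        ).codes
        means = np.asarray(design.impact["means"], dtype=float)[codes]
        sds = np.sqrt(np.asarray(design.impact["variances"], dtype=float))[codes]
    theta = means + sds * rng.standard_normal(n)

    a, d = person_item_params(design, cov)
    values = np.empty((n, j), dtype=np.int64)
    for jj in range(j):
        k = len(design.intercepts[jj])
        kk = np.arange(k + 1, dtype=float)
        cum_d = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(d[:, jj, :k], axis=1)], axis=1
        )
        z = kk[None, :] * (a[:, jj] * theta)[:, None] + cum_d
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        values[:, jj] = (p.cumsum(axis=1) < rng.uniform(size=(n, 1))).sum(axis=1)

    resp = ResponseMatrix(values, design.n_categories)
    truth = {
        "design": design,
        "theta": theta,
        "person_slopes": a,
        "person_intercepts": d,
        "dif_free": all(eff.size == 0.0 for eff in design.dif),
    }
    return resp, cov, truth


def _fit_for_study(resp, cov, fit_spec):
    model = fit_spec.get("model", "rasch_cml")
    impact_col = fit_spec.get("impact")
    impact = cov[impact_col].to_numpy() if impact_col else None
    if model == "rasch_cml":
        return fit_rasch_cml(resp)
    return fit_mml(
        resp,
        model.replace("_mml", ""),
        impact=impact,
        maxit=fit_spec.get("maxit", 500),
        tol=fit_spec.get("tol", 1e-5),
        n_quad=fit_spec.get("n_quad", 61),
    )


def rejection_rate_study(
    design: SimulationDesign,
    fit_spec: dict,
    test_spec: dict,
    n_reps: int,
    alpha=0.05,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of one test under one generating design.

    Each replication re-draws data (streams spawned from ``design.seed``),
    refits the model and recomputes the test; failed fits are counted and
    excluded. Returns one row per alpha with the rate and its binomial
    standard error.
    """
    if n_reps < 2:
        raise StudyError("need at least 2 replications")
    alphas = np.atleast_1d(np.asarray(alpha, dtype=float))
    children = np.random.SeedSequence(design.seed).spawn(n_reps)
    pvals = []
    n_failed = 0
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rep_design = replace(design, seed=rep_seed)
        try:
            resp, cov, _ = simulate_responses(rep_design)
            fit = _fit_for_study(resp, cov, fit_spec)
            levels = None
            spec = next(
                (c for c in design.covariates if c.name == test_spec["covariate"]), None
            )
            if spec is not None and spec.kind != "continuous":
                levels = list(spec.levels)
            result = run_test(
                fit,
                resp,
                cov[test_spec["covariate"]].to_numpy(),
                kind=test_spec["kind"],
                functional=test_spec["functional"],
                pars=test_spec.get("pars"),
                levels=levels,
                trim=test_spec.get("trim", (0.1, 0.9)),
                reps=test_spec.get("reps", 10_000),
                seed=test_spec.get("seed", 0),
            )
            pvals.append(result.p_value)
        except Exception:
            n_failed += 1
    if not pvals:
        raise StudyError("every replication failed to fit or test")
    pvals = np.asarray(pvals)
    rows = []
    for al in alphas:
        rate = float(np.mean(pvals <= al))
        rows.append(
            {
                "alpha": float(al),
                "rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / pvals.size)),
                "n_used": int(pvals.size),
                "n_failed": n_failed,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["p_values"] = pvals
    return out


def design_from_config(cfg: dict) -> SimulationDesign:
    """Build a SimulationDesign from the flat config dialect.

    Item parameters: ``difficulties`` (Rasch) or ``slopes`` plus either
    ``intercepts`` (dichotomous) or per-item ``intercepts.<j>`` lists (GPCM,
    1-based item index). Covariates use dotted keys
    ``covariate.<name>.<field>``; DIF effects ``dif.<k>.<field>`` with 1-based
    item/threshold indices; impact ``impact.covariate/means/variances``.
    """
    def aslist(v):
        return v if isinstance(v, list) else [v]

    model = cfg.get("model", "rasch")
    nested: dict = {}
    for key, value in cfg.items():
        parts = key.split(".")
        node = nested
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value

    covs = []
    for name, sub in nested.get("covariate", {}).items():
        covs.append(
            CovariateSpec(
                name=name,
                kind=sub.get("kind", "continuous"),
                distribution=sub.get("distribution", "normal"),
                params=tuple(aslist(sub.get("params", [0.0, 1.0]))),
                levels=tuple(str(v) for v in aslist(sub.get("levels", []))),
                probs=tuple(aslist(sub.get("probs", []))),
            )
        )

    if "difficulties" in cfg:
        slopes = None
        intercepts = tuple((-float(b),) for b in aslist(cfg["difficulties"]))
    elif "intercepts" in cfg:
        intercepts = tuple((float(x),) for x in aslist(cfg["intercepts"]))
        slopes = None
    else:
        by_item = nested.get("intercepts", None)
        if isinstance(by_item, dict):
            items = sorted(int(k) for k in by_item)
            intercepts = tuple(tuple(float(x) for x in aslist(by_item[str(j)])) for j in items)
        else:
            raise ConfigError("design needs difficulties, intercepts or intercepts.<j>")
    if slopes is None:
        slopes = tuple(float(a) for a in aslist(cfg["slopes"])) if "slopes" in cfg else tuple(
            [1.0] * len(intercepts)
        )

    impact = None
    if "impact" in nested and isinstance(nested["impact"], dict):
        sub = nested["impact"]
        impact = {
            "covariate": sub["covariate"],
            "means": [float(x) for x in aslist(sub["means"])],
            "variances": [float(x) for x in aslist(sub["variances"])],
        }

    difs = []
    for _, sub in sorted(nested.get("dif", {}).items()):
        difs.append(
            DifSpec(
                item=int(sub["item"]) - 1,
                param=sub.get("param", "intercept"),
                covariate=sub["covariate"],
                form=sub.get("form", "shift"),
                size=float(sub.get("size", 0.0)),
                threshold_index=int(sub.get("threshold", 1)) - 1,
                affected_levels=tuple(str(v) for v in aslist(sub.get("levels", []))),
            )
        )

    return SimulationDesign(
        model=model,
        slopes=slopes,
        intercepts=intercepts,
        n_persons=int(cfg["n_persons"]),
        seed=int(cfg["seed"]),
        covariates=tuple(covs),
        impact=impact,
        dif=tuple(difs),
    )
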