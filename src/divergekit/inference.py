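"""Model competition linking phenotypes to selection indices, and Mantel
tests linking phenotypic distance to genetic differentiation.

Candidate models are compared with AICc (small-sample Akaike criterion) and
Akaike weights; models within 2 AICc units of the best are treated as
equally viable.  Individual-level traits use a Gaussian random-intercept
model (population as the grouping factor) fitted by maximum likelihood with
the variance ratio profiled by 1-D optimisation; population-level traits
(allometric coefficients) use ordinary least squares.  When the null model
is competitive, a Mantel permutation test asks whether between-population
phenotypic distance (Cohen's d) instead tracks neutral genetic distance
(Jost's D).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ModelFit",
    "ModelRanking",
    "MantelResult",
    "aicc",
    "rank_models",
    "fit_random_intercept",
    "fit_population_regression",
    "effect_size_r",
    "cohens_d_matrix",
    "abs_diff_matrix",
    "mantel_test",
    "candidate_models_individual",
    "candidate_models_population",
    "SEXUAL_INDICES",
    "NATURAL_INDICES",
]

#: Index names classed as sexual-selection predictors.
SEXUAL_INDICES = ("sex_ratio", "intrasexual_density", "total_density")
#: Index names classed as natural-selection (predation) predictors.
NATURAL_INDICES = ("flight_distance", "predator_strikes")


@dataclass
class ModelFit:
    model_label: str
    loglik: float
    k: int
    n: int
    aicc: float
    coefficients: Dict[str, Tuple[float, float]]  # term -> (estimate, t)
    kind: str = "ols"  # "ols" or "mixed"
    n_groups: Optional[int] = None
    variance_components: Optional[Dict[str, float]] = None
    terms: Tuple[str, ...] = ()


@dataclass
class ModelRanking:
    fits: List[ModelFit]
    delta_aicc: np.ndarray
    weights: np.ndarray
    supported: np.ndarray  # delta <= 2.0
    effect_sizes: List[Dict[str, float]] = field(default_factory=list)

    def best(self) -> ModelFit:
        return self.fits[0]

    def null_supported(self, label: str = "Null") -> bool:
        """True iff the no-predictor model sits within 2 AICc units of the
        best model (the trigger for a follow-up Mantel test)."""
        for fit, sup in zip(self.fits, self.supported):
            if fit.model_label == label:
                return bool(sup)
        raise ValueError(f"no model labelled {label!r} in ranking")

    def to_frame(self):
        import pandas as pd

        rows = []
        for fit, d, w, es in zip(
                self.fits, self.delta_aicc, self.weights,
                self.effect_sizes or [{}] * len(self.fits)):
            rows.append({
                "model": fit.model_label,
                "aicc": fit.aicc,
                "delta_aicc": d,
                "weight": w,
                "r_sexual": es.get("r_sexual", np.nan),
                "r_natural": es.get("r_natural", np.nan),
            })
        return pd.DataFrame(rows)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2*loglik + 2k + 2k(k+1)/(n - k - 1); needs n > k + 1."""
    if n <= k + 1:
        raise ValueError(
            f"AICc penalty infinite: n={n} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(fits: Sequence[ModelFit]) -> ModelRanking:
    """Order fits by AICc; attach delta-AICc, Akaike weights, and per-model
    sexual/natural effect sizes for supported models."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need >= 2 candidate models to rank")
    n_set = {f.n for f in fits}
    if len(n_set) != 1:
        raise ValueError(
            f"models fit to different sample sizes {sorted(n_set)}; "
            "AICc comparison invalid")
    order = np.argsort([f.aicc for f in fits], kind="stable")
    fits = [fits[i] for i in order]
    a = np.array([f.aicc for f in fits])
    delta = a - a[0]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    effect_sizes = []
    for fit in fits:
        es = {}
        for term in fit.terms:
            if term in SEXUAL_INDICES:
                es["r_sexual"] = effect_size_r(fit, term)
            elif term in NATURAL_INDICES:
                es["r_natural"] = effect_size_r(fit, term)
        effect_sizes.append(es)
    return ModelRanking(fits=fits, delta_aicc=delta, weights=w,
                        supported=delta <= 2.0, effect_sizes=effect_sizes)


# ---------------------------------------------------------------------------
# Random-intercept ML fit (profiled variance ratio)

def _profile_loglik(ln_lambda: float, y, X, group_sizes, group_slices):
    """ML log-likelihood with lambda = sigma_u^2/sigma_e^2 fixed; beta and
    sigma_e^2 profiled out in closed form (Sherman-Morrison per block)."""
    lam = math.exp(ln_lambda)
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    blocks = []
    for (sl, m) in zip(group_slices, group_sizes):
        Xg = X[sl]
        yg = y[sl]
        c = lam / (1.0 + m * lam)
        xs = Xg.sum(axis=0)
        ys = yg.sum()
        XtVX += Xg.T @ Xg - c * np.outer(xs, xs)
        XtVy += Xg.T @ yg - c * xs * ys
        logdet += math.log1p(m * lam)
        blocks.append((Xg, yg, c, xs, ys))
    beta = np.linalg.solve(XtVX, XtVy)
    rss = 0.0
    for Xg, yg, c, xs, ys in blocks:
        rg = yg - Xg @ beta
        rs = rg.sum()
        rss += rg @ rg - c * rs * rs
    sigma2 = rss / n
    ll = -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * logdet - 0.5 * n
    return ll, beta, sigma2, XtVX


def fit_random_intercept(y, X, groups, terms=("intercept",),
                         model_label: str = "") -> ModelFit:
    """ML fit of y = X beta + u_group + eps with a single random intercept.

    The variance ratio lambda = sigma_u^2/sigma_e^2 is profiled by bounded
    1-D search on ln(lambda) (tolerance 1e-8), with the lambda -> 0 (plain
    OLS) boundary checked explicitly.  k counts the fixed effects plus the
    two variance parameters.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x p matching y")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    labels, inverse = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need >= 2 groups for a random intercept")
    order = np.argsort(inverse, kind="stable")
    y_s, X_s, inv_s = y[order], X[order], inverse[order]
    group_sizes = np.bincount(inv_s)
    bounds_idx = np.concatenate([[0], np.cumsum(group_sizes)])
    group_slices = [slice(bounds_idx[i], bounds_idx[i + 1])
                    for i in range(labels.size)]

    def neg(ln_lam):
        return -_profile_loglik(ln_lam, y_s, X_s, group_sizes, group_slices)[0]

    res = optimize.minimize_scalar(
        neg, bounds=(-30.0, 15.0), method="bounded",
        options={"xatol": 1e-8})
    # lambda -> 0 boundary (no between-group variance): compare with OLS
    ll_opt = -res.fun
    ll_zero = -neg(-30.0)
    ln_lam = res.x if ll_opt >= ll_zero else -30.0
    ll, beta, sigma2, XtVX = _profile_loglik(
        ln_lam, y_s, X_s, group_sizes, group_slices)
    lam = math.exp(ln_lam)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    coefficients = {
        term: (float(beta[i]), float(tvals[i]))
        for i, term in enumerate(terms)
    }
    k = p + 2
    return ModelFit(
        model_label=model_label or "+".join(t for t in terms
                                            if t != "intercept") or "Null",
        loglik=float(ll), k=k, n=n, aicc=aicc(float(ll), k, n),
        coefficients=coefficients, kind="mixed", n_groups=int(labels.size),
        variance_components={
            "sigma2_residual": float(sigma2),
            "sigma2_group": float(lam * sigma2),
        },
        terms=tuple(t for t in terms if t != "intercept"),
    )


def fit_population_regression(y, X=None, terms=("intercept",),
                              model_label: str = "") -> ModelFit:
    """Gaussian OLS on population-level values (e.g. allometric
    coefficients); k counts the coefficients plus the residual variance."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 populations")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n  # ML variance
    if sigma2 <= 0:
        # perfect fit: likelihood unbounded; flag with +inf loglik
        raise ValueError("zero residual variance: Gaussian loglik unbounded")
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    cov_beta = sigma2 * n / max(n - p, 1) * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    coefficients = {
        term: (float(beta[i]), float(tvals[i]))
        for i, term in enumerate(terms)
    }
    k = p + 1
    return ModelFit(
        model_label=model_label or "+".join(t for t in terms
                                            if t != "intercept") or "Null",
        loglik=float(ll), k=k, n=n, aicc=aicc(float(ll), k, n),
        coefficients=coefficients, kind="ols",
        terms=tuple(t for t in terms if t != "intercept"),
    )


def effect_size_r(fit: ModelFit, term: str) -> float:
    """Signed effect size r = t / sqrt(t^2 + df) for one model term.

    For mixed fits the predictors vary only between populations, so df is
    (number of groups - number of fixed effects); for OLS it is n - p.
    """
    if term not in fit.coefficients:
        raise KeyError(f"term {term!r} not in model {fit.model_label!r}")
    _, t = fit.coefficients[term]
    p_fixed = len(fit.coefficients)
    if fit.kind == "mixed":
        df = (fit.n_groups or 0) - p_fixed
    else:
        df = fit.n - p_fixed
    if df <= 0:
        raise ValueError(f"nonpositive df ({df}) for effect size")
    return float(t / math.sqrt(t * t + df))


def candidate_models_individual(y, groups, indices: Dict[str, Dict[str, float]]
                                ) -> List[ModelFit]:
    """The 12-model candidate set for an individual-level trait.

    ``indices`` maps population -> {index name -> value}; values are
    broadcast to individuals.  Models: Null, each single index, and each
    sexual x natural pair.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n = y.size

    def design(term_names):
        cols = [np.ones(n)]
        for t in term_names:
            cols.append(np.array([indices[g][t] for g in groups], dtype=float))
        return np.column_stack(cols)

    specs: List[Tuple[str, Tuple[str, ...]]] = [("Null", ())]
    for t in SEXUAL_INDICES + NATURAL_INDICES:
        specs.append((t, (t,)))
    for s in SEXUAL_INDICES:
        for nat in NATURAL_INDICES:
            specs.append((f"{s}+{nat}", (s, nat)))
    fits = []
    for label, term_names in specs:
        fits.append(fit_random_intercept(
            y, design(term_names), groups,
            terms=("intercept",) + term_names, model_label=label))
    return fits


def candidate_models_population(y_by_pop: Dict[str, float],
                                indices: Dict[str, Dict[str, float]],
                                ) -> List[ModelFit]:
    """Candidate set for a population-level trait (head-crest allometric
    coefficients): Null plus the sexual-selection indices only, fitted by
    OLS across populations."""
    pops = list(y_by_pop)
    y = np.array([y_by_pop[p] for p in pops], dtype=float)
    n = len(pops)
    fits = [fit_population_regression(y, model_label="Null")]
    for t in SEXUAL_INDICES:
        X = np.column_stack([
            np.ones(n),
            np.array([indices[p][t] for p in pops], dtype=float),
        ])
        fits.append(fit_population_regression(
            y, X, terms=("intercept", t), model_label=t))
    return fits


# ---------------------------------------------------------------------------
# Distance matrices and the Mantel test

def cohens_d_matrix(values_by_pop: Dict[str, Sequence[float]]
                    ) -> Tuple[List[str], np.ndarray]:
    """Pairwise |mean difference| / pooled SD between populations.

    s_pooled^2 = ((n_i - 1) s_i^2 + (n_j - 1) s_j^2) / (n_i + n_j - 2).
    """
    pops = list(values_by_pop)
    arrays = {p: np.asarray(values_by_pop[p], dtype=float) for p in pops}
    for p, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"population {p!r} needs >= 2 individuals")
    k = len(pops)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[pops[i]], arrays[pops[j]]
            na, nb = a.size, b.size
            sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                   / (na + nb - 2))
            if sp2 <= 0:
                raise ValueError(
                    f"zero pooled SD between {pops[i]!r} and {pops[j]!r}")
            d = abs(a.mean() - b.mean()) / math.sqrt(sp2)
            mat[i, j] = mat[j, i] = d
    return pops, mat


def abs_diff_matrix(value_by_pop: Dict[str, float]
                    ) -> Tuple[List[str], np.ndarray]:
    """|difference| distance for population-level coefficients (allometric
    elevation/exponent have no within-population SD, so Cohen's d is not
    defined; this is the documented fallback)."""
    pops = list(value_by_pop)
    v = np.array([value_by_pop[p] for p in pops], dtype=float)
    mat = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(mat, 0.0)
    return pops, mat


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations_used: int
    exhaustive: bool
    beta_intercept: float
    beta_slope: float
    beta_intercept_ci: Tuple[float, float]
    beta_slope_ci: Tuple[float, float]


def _check_distance_matrix(mat, name):
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return mat


def mantel_test(pheno_dist, genetic_dist, n_perm: int = 10_000,
                seed: Optional[int] = None,
                exhaustive_max: int = 7) -> MantelResult:
    """Two-sided Mantel test of matrix correlation.

    r is the Pearson correlation over upper-triangle pairs; the null
    distribution shuffles the phenotypic matrix's rows and columns
    simultaneously.  With at most ``exhaustive_max`` populations all n!
    relabelings are enumerated exactly; otherwise ``n_perm`` random shuffles
    are drawn and p = (#{|r_perm| >= |r_obs|} + 1)/(n_perm + 1).  The
    reported betas come from OLS of phenotypic on genetic pairwise distance
    (pairs are not independent; CIs are descriptive).
    """
    A = _check_distance_matrix(pheno_dist, "pheno_dist")
    B = _check_distance_matrix(genetic_dist, "genetic_dist")
    if A.shape != B.shape:
        raise ValueError("matrices must have identical shape")
    k = A.shape[0]
    if k < 3:
        raise ValueError("need >= 3 populations")
    iu = np.triu_indices(k, 1)
    x = B[iu]  # genetic distance is the predictor
    yv = A[iu]
    if x.std() == 0 or yv.std() == 0:
        raise ValueError("constant distances: Mantel r undefined")
    r_obs = float(np.corrcoef(x, yv)[0, 1])

    tol = 1e-12
    if k <= exhaustive_max:
        count = 0
        total = 0
        for perm in itertools.permutations(range(k)):
            Ap = A[np.ix_(perm, perm)]
            r_p = np.corrcoef(Ap[iu], x)[0, 1]
            if abs(r_p) >= abs(r_obs) - tol:
                count += 1
            total += 1
        p = count / total
        n_used = total
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(k)
            Ap = A[np.ix_(perm, perm)]
            r_p = np.corrcoef(Ap[iu], x)[0, 1]
            if abs(r_p) >= abs(r_obs) - tol:
                count += 1
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
        exhaustive = False

    lr = stats.linregress(x, yv)
    df = x.size - 2
    tcrit = stats.t.ppf(0.975, df)
    b_ci = (lr.slope - tcrit * lr.stderr, lr.slope + tcrit * lr.stderr)
    a_ci = (lr.intercept - tcrit * lr.intercept_stderr,
            lr.intercept + tcrit * lr.intercept_stderr)
    return MantelResult(
        r=r_obs, p=float(p), n_permutations_used=n_used,
        exhaustive=exhaustive,
        beta_intercept=float(lr.intercept), beta_slope=float(lr.slope),
        beta_intercept_ci=(float(a_ci[0]), float(a_ci[1])),
        beta_slope_ci=(float(b_ci[0]), float(b_ci[1])),
    )
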