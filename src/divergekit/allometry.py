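"""Standardized (reduced) major axis allometry of ornament size on body size.

On the ln-ln scale the power law y = a * x^b is linear with slope b (the
allometric exponent) and, after centring body length on a grand mean,
intercept a (the allometric elevation).  SMA minimises deviations in both
variables; its slope is sign(r) * sd(y)/sd(x).  Ornaments under sexual
selection are expected to show exponents of at least 1.5 that also exceed a
non-sexually-selected control trait (here the ventral fin), judged by 95%
confidence-interval separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AllometryFit",
    "sma_fit",
    "slope_ci",
    "elevation_ci_bootstrap",
    "ci_overlap",
    "classify_ornament",
    "sex_dimorphism_elevation",
    "SEXUALLY_SELECTED",
    "INDISTINGUISHABLE_FROM_CONTROL",
    "BELOW_THRESHOLD",
]

SEXUALLY_SELECTED = "sexually-selected signature"
INDISTINGUISHABLE_FROM_CONTROL = "indistinguishable from control"
BELOW_THRESHOLD = "below threshold"


@dataclass
class AllometryFit:
    """SMA fit of one trait for one population and sex.

    ``elevation_a`` is the fitted value of y at ``grand_mean_x`` (the ln body
    length grand mean used for centring), ``exponent_b`` the SMA slope.
    """

    trait: str
    population: str
    sex: str
    n: int
    elevation_a: float
    exponent_b: float
    r: float
    grand_mean_x: float
    a_ci: Optional[Tuple[float, float]] = None
    b_ci: Optional[Tuple[float, float]] = None


def sma_fit(x, y, grand_mean_x=None, *, trait="", population="", sex="",
            alpha=0.05, n_bootstrap=0, rng=None) -> AllometryFit:
    """Fit a standardized major axis line to (x, y).

    x should be ln body length and y a linearized (ln sqrt area) trait.
    ``grand_mean_x`` is the centring point for the elevation; it defaults to
    mean(x) but for cross-population comparisons must be the grand mean over
    all populations of the same sex.  With ``n_bootstrap`` > 0 a seeded
    percentile bootstrap supplies the elevation CI.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 points, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y: SMA fit is degenerate")
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        raise ValueError("r is exactly 0: SMA slope sign is undefined")
    if grand_mean_x is None:
        grand_mean_x = float(x.mean())
    b = float(np.sign(r) * sy / sx)
    a = float(y.mean() - b * (x.mean() - grand_mean_x))
    b_ci = slope_ci(b, r, n, alpha)
    a_ci = None
    if n_bootstrap:
        a_ci = elevation_ci_bootstrap(
            x, y, grand_mean_x, alpha=alpha, n_bootstrap=n_bootstrap, rng=rng)
    return AllometryFit(
        trait=trait, population=population, sex=sex, n=n,
        elevation_a=a, exponent_b=b, r=r, grand_mean_x=float(grand_mean_x),
        a_ci=a_ci, b_ci=b_ci,
    )


def slope_ci(b: float, r: float, n: int, alpha: float = 0.05
             ) -> Tuple[float, float]:
    """Classical (Jolicoeur/Pitman) SMA slope confidence interval.

    B = t^2 * (1 - r^2)/(n - 2); the bounds are b*(sqrt(B+1) -/+ sqrt(B)),
    returned sorted so the interval always contains b.  |r| = 1 collapses
    the interval to (b, b).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return (b, b)
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    B = t * t * (1.0 - r * r) / (n - 2)
    lo = b * (np.sqrt(B + 1.0) - np.sqrt(B))
    hi = b * (np.sqrt(B + 1.0) + np.sqrt(B))
    return (float(min(lo, hi)), float(max(lo, hi)))


def elevation_ci_bootstrap(x, y, grand_mean_x, *, alpha=0.05,
                           n_bootstrap=2000, rng=None) -> Tuple[float, float]:
    """Percentile-bootstrap CI for the SMA elevation at ``grand_mean_x``.

    Resamples individuals with replacement; degenerate resamples (zero
    variance or r = 0) are redrawn.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(rng)
    n = x.size
    estimates = np.empty(n_bootstrap)
    filled = 0
    attempts = 0
    while filled < n_bootstrap:
        attempts += 1
        if attempts > 50 * n_bootstrap:
            raise RuntimeError("bootstrap failed: data nearly degenerate")
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        sx = xb.std(ddof=1)
        sy = yb.std(ddof=1)
        if sx == 0 or sy == 0:
            continue
        r = np.corrcoef(xb, yb)[0, 1]
        if r == 0 or not np.isfinite(r):
            continue
        b = np.sign(r) * sy / sx
        estimates[filled] = yb.mean() - b * (xb.mean() - grand_mean_x)
        filled += 1
    lo, hi = np.quantile(estimates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(lo), float(hi))


def ci_overlap(interval1: Tuple[float, float],
               interval2: Tuple[float, float]) -> bool:
    """True iff the two closed intervals share at least one point."""
    lo1, hi1 = interval1
    lo2, hi2 = interval2
    if lo1 > hi1 or lo2 > hi2:
        raise ValueError("intervals must satisfy lo <= hi")
    return max(lo1, lo2) <= min(hi1, hi2)


def classify_ornament(fit: AllometryFit, control: AllometryFit,
                      threshold: float = 1.5) -> str:
    """Classify a trait's allometry against the sexually-selected benchmark.

    A sexually-selected signature requires the exponent to reach the
    threshold (inclusive) AND its 95% CI to be separated from the control
    trait's CI.  Below-threshold exponents are reported as such regardless
    of CI separation.
    """
    if fit.population != control.population or fit.sex != control.sex:
        raise ValueError(
            "fit and control must come from the same population and sex")
    if fit.b_ci is None or control.b_ci is None:
        raise ValueError("both fits must carry slope confidence intervals")
    if fit.exponent_b < threshold:
        return BELOW_THRESHOLD
    if ci_overlap(fit.b_ci, control.b_ci):
        return INDISTINGUISHABLE_FROM_CONTROL
    return SEXUALLY_SELECTED


def sex_dimorphism_elevation(fit_m: AllometryFit, fit_f: AllometryFit) -> str:
    """Compare male vs female elevation of the same trait in one population.

    Returns 'male-biased' or 'female-biased' when the elevations differ in
    the stated direction with non-overlapping CIs, else 'indistinguishable'.
    """
    if fit_m.trait != fit_f.trait or fit_m.population != fit_f.population:
        raise ValueError("fits must describe the same trait and population")
    if fit_m.a_ci is None or fit_f.a_ci is None:
        raise ValueError("both fits must carry elevation confidence intervals")
    if not ci_overlap(fit_m.a_ci, fit_f.a_ci):
        if fit_m.elevation_a > fit_f.elevation_a:
            return "male-biased"
        if fit_f.elevation_a > fit_m.elevation_a:
            return "female-biased"
    return "indistinguishable"
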