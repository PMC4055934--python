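"""Synthetic generators for all five input streams, with known ground truth.

The generators emulate the study design: per-individual morphometrics
following a power-law allometry with multiplicative (log-normal) noise,
Poisson quadrate censuses calibrated so the two-level sex-ratio and density
indices are unbiased for their targets, FID trials started at 12-13 paces,
multinomial prey-model damage categories, and Dirichlet-multinomial
island-model genotypes whose differentiation level is set by a single
concentration parameter (large theta => tight around the ancestral
frequencies => near-panmixia).

Every generator is a pure function of (scenarios, seed); the global seed is
split per generator through numpy SeedSequence sub-keys (1 = morphometrics,
2 = surveys, 3 = genotypes) so stages are individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .records import (
    MISSING,
    NOMINAL_QUADRATE_AREA_M2,
    FIDTrial,
    GenotypeTable,
    MorphRecord,
    PredationCounts,
    QuadrateObservation,
)

__all__ = [
    "PopulationScenario",
    "default_scenarios",
    "simulate_morphometrics",
    "simulate_surveys",
    "simulate_genotypes",
    "expected_inverse_positive_poisson",
]


def _default_allometry() -> Dict[Tuple[str, str], Tuple[float, float]]:
    """(elevation, exponent) on the ln-linearized scale per (trait, sex);
    stylised around the magnitudes typical of the study system."""
    return {
        ("crest", "M"): (1.10, 2.30),
        ("dorsal", "M"): (2.70, 1.65),
        ("ventral", "M"): (2.40, 1.28),
        ("dorsal", "F"): (2.40, 1.40),
        ("ventral", "F"): (2.25, 1.22),
    }


@dataclass
class PopulationScenario:
    """Ground truth for one simulated population.

    Allometry is parameterised on the linearized scale:
    ln sqrt(area) = a + b * (ln L - length_log_mean) + N(0, noise_log_sd),
    so ``a`` is the elevation at the population's mean ln body length and
    ``b`` the allometric exponent.  ``theta_divergence`` scales the
    Dirichlet concentration of population allele frequencies around the
    ancestral vector: larger theta means less genetic differentiation;
    ``None`` means no perturbation at all (exact panmixia).
    """

    population: str
    n_per_sex: int = 25
    allometry: Dict[Tuple[str, str], Tuple[float, float]] = field(
        default_factory=_default_allometry)
    length_log_mean: float = math.log(60.0)  # ~60 mm standard length
    length_log_sd: float = 0.15
    noise_log_sd: float = 0.05
    sex_ratio_target: float = 1.5
    density_target: float = 16.0  # adults per m^2
    strike_prob: float = 0.10  # P(category 4 | category != 5)
    cat5_prob: float = 0.05
    fid_mean_paces: float = 5.0
    delta_rg_mean: float = 0.4
    prop_coloured_mean: float = 0.5
    theta_divergence: Optional[float] = 1000.0
    n_quadrates: int = 8
    n_observations: int = 9
    n_fid_per_sex: int = 25
    n_models: int = 40
    year: int = 2011

    def __post_init__(self) -> None:
        if self.n_per_sex < 2:
            raise ValueError("n_per_sex must be >= 2")
        if self.noise_log_sd < 0:
            raise ValueError("noise_log_sd must be nonnegative")
        if not (0.0 <= self.strike_prob <= 1.0):
            raise ValueError("strike_prob must lie in [0, 1]")
        if self.sex_ratio_target <= 0 or self.density_target <= 0:
            raise ValueError("sex_ratio_target and density_target must be > 0")
        if self.theta_divergence is not None and self.theta_divergence <= 0:
            raise ValueError("theta_divergence must be positive or None")


def default_scenarios() -> List[PopulationScenario]:
    """Five populations in the study's qualitative regime: near-panmictic
    genetics, male-biased sex ratios of varying strength, and a head-crest
    exponent that rises with the sex ratio (the sexual-selection pattern)."""
    spec = [
        # (name, sex_ratio, strike_prob, crest_b, delta_rg, fid_mean)
        ("Pop1", 1.9, 0.08, 2.50, 0.45, 6.0),
        ("Pop2", 1.6, 0.14, 2.24, 0.35, 5.5),
        ("Pop3", 0.9, 0.05, 1.70, 0.60, 4.0),
        ("Pop4", 2.1, 0.10, 2.62, 0.40, 5.0),
        ("Pop5", 1.4, 0.18, 2.14, 0.30, 6.5),
    ]
    out = []
    for name, ratio, strike, crest_b, drg, fid in spec:
        allo = _default_allometry()
        a_crest, _ = allo[("crest", "M")]
        allo[("crest", "M")] = (a_crest, crest_b)
        out.append(PopulationScenario(
            population=name, sex_ratio_target=ratio, strike_prob=strike,
            delta_rg_mean=drg, fid_mean_paces=fid, allometry=allo,
        ))
    return out


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# Morphometrics

TRAIT_FIELD = {
    "crest": "crest_area_mm2",
    "dorsal": "dorsal_area_mm2",
    "ventral": "ventral_area_mm2",
}


def simulate_morphometrics(scenarios: Sequence[PopulationScenario],
                           seed: int) -> List[MorphRecord]:
    """Draw per-individual morphometric and colour records.

    Body lengths are log-normal; each area satisfies
    sqrt(area) = exp(a) * (L / exp(length_log_mean))^b * eps with eps
    log-normal(0, noise_log_sd), i.e. the linearized ln-ln model is exactly
    linear with Gaussian error.  Colour channels are drawn so the fin-minus-
    body R/G difference has mean delta_rg_mean.
    """
    if not scenarios:
        raise ValueError("scenarios must be non-empty")
    rng = _rng(seed, 1)
    records: List[MorphRecord] = []
    for sc in scenarios:
        for sex in ("M", "F"):
            ln_len = rng.normal(sc.length_log_mean, sc.length_log_sd,
                                size=sc.n_per_sex)
            areas = {}
            for (trait, tsex), (a, b) in sc.allometry.items():
                if tsex != sex:
                    continue
                ln_half = (a + b * (ln_len - sc.length_log_mean)
                           + rng.normal(0.0, sc.noise_log_sd,
                                        size=sc.n_per_sex))
                areas[trait] = np.exp(2.0 * ln_half)
            body_ratio = rng.normal(1.0, 0.03, size=sc.n_per_sex)
            fin_ratio = (body_ratio + sc.delta_rg_mean
                         + rng.normal(0.0, 0.05, size=sc.n_per_sex))
            fin_G = rng.normal(90.0, 5.0, size=sc.n_per_sex)
            body_G = rng.normal(90.0, 5.0, size=sc.n_per_sex)
            conc = 20.0
            prop = rng.beta(sc.prop_coloured_mean * conc,
                            (1.0 - sc.prop_coloured_mean) * conc,
                            size=sc.n_per_sex)
            for i in range(sc.n_per_sex):
                records.append(MorphRecord(
                    individual_id=f"{sc.population}_{sex}{i:03d}",
                    population=sc.population,
                    sex=sex,
                    year=sc.year,
                    body_length_mm=float(np.exp(ln_len[i])),
                    dorsal_area_mm2=float(areas["dorsal"][i]),
                    crest_area_mm2=(float(areas["crest"][i])
                                    if sex == "M" else None),
                    ventral_area_mm2=float(areas["ventral"][i]),
                    prop_fin_coloured=float(np.clip(prop[i], 0.0, 1.0)),
                    fin_R=float(np.clip(fin_ratio[i] * fin_G[i], 0.0, 255.0)),
                    fin_G=float(np.clip(fin_G[i], 1.0, 255.0)),
                    body_R=float(np.clip(body_ratio[i] * body_G[i],
                                         0.0, 255.0)),
                    body_G=float(np.clip(body_G[i], 1.0, 255.0)),
                ))
    return records


# ---------------------------------------------------------------------------
# Surveys

def expected_inverse_positive_poisson(mu: float, tol: float = 1e-14) -> float:
    """E[1/F | F > 0] for F ~ Poisson(mu), by series summation."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    total = 0.0
    log_term = -mu  # ln of mu^k e^-mu / k! at k=0
    term = math.exp(-mu)
    k = 0
    while True:
        k += 1
        term *= mu / k
        contrib = term / k
        total += contrib
        if k > mu and contrib < tol * max(total, 1e-300):
            break
        if k > 10_000_000:  # pragma: no cover
            break
    return total / (1.0 - math.exp(-mu))


def _calibrate_poisson_means(sex_ratio_target: float, density_target: float,
                             area: float) -> Tuple[float, float]:
    """Solve for (mu_m, mu_f) such that the expected per-observation M/F
    ratio (conditional on F > 0) equals the target and total adult density
    equals density_target.

    A raw mu_m/mu_f = target choice is biased because
    E[M/F | F>0] = mu_m * E[1/F | F>0] > mu_m/mu_f.
    """
    mu_total = density_target * area

    def gap(mu_f):
        mu_m = mu_total - mu_f
        return mu_m * expected_inverse_positive_poisson(mu_f) - sex_ratio_target

    lo, hi = 1e-9, mu_total - 1e-9
    if gap(lo) < 0:
        raise ValueError(
            "density_target too low to realise sex_ratio_target")
    mu_f = optimize.brentq(gap, lo, hi, xtol=1e-12)
    return mu_total - mu_f, mu_f


def simulate_surveys(scenarios: Sequence[PopulationScenario], seed: int
                     ) -> Tuple[List[QuadrateObservation], List[FIDTrial],
                                List[PredationCounts]]:
    """Draw quadrate censuses, FID trials and prey-model damage tallies.

    Quadrate counts are Poisson with means calibrated so the two-level
    sex-ratio index is unbiased for ``sex_ratio_target`` and total adult
    density matches ``density_target``.  FID trials start at 12-13 paces
    with Poisson flight distances of mean ``fid_mean_paces`` (censored at
    the start distance).  Damage categories are multinomial with
    P(category 4 | not category 5) = ``strike_prob``.
    """
    if not scenarios:
        raise ValueError("scenarios must be non-empty")
    rng = _rng(seed, 2)
    area = NOMINAL_QUADRATE_AREA_M2
    quadrates: List[QuadrateObservation] = []
    fid_trials: List[FIDTrial] = []
    predation: List[PredationCounts] = []
    for sc in scenarios:
        mu_m, mu_f = _calibrate_poisson_means(
            sc.sex_ratio_target, sc.density_target, area)
        mu_juv = 0.3 * (mu_m + mu_f)
        for q in range(sc.n_quadrates):
            for o in range(sc.n_observations):
                quadrates.append(QuadrateObservation(
                    population=sc.population,
                    quadrate_id=f"{sc.population}_Q{q + 1}",
                    observation_index=o + 1,
                    n_males=int(rng.poisson(mu_m)),
                    n_females=int(rng.poisson(mu_f)),
                    n_juveniles=int(rng.poisson(mu_juv)),
                    exposed_area_m2=area,
                ))
        for sex in ("M", "F"):
            d_start = rng.integers(12, 14, size=sc.n_fid_per_sex)
            fid = rng.poisson(sc.fid_mean_paces, size=sc.n_fid_per_sex)
            fid = np.minimum(fid, d_start)
            for ds, f in zip(d_start, fid):
                fid_trials.append(FIDTrial(
                    population=sc.population, sex=sex,
                    d_start_paces=int(ds), d_flee_paces=int(ds - f)))
        p5 = sc.cat5_prob
        base123 = np.array([0.60, 0.25, 0.15])
        probs = np.concatenate([
            (1.0 - p5) * (1.0 - sc.strike_prob) * base123,
            [(1.0 - p5) * sc.strike_prob, p5],
        ])
        counts = rng.multinomial(sc.n_models, probs)
        predation.append(PredationCounts(
            population=sc.population,
            n_cat1=int(counts[0]), n_cat2=int(counts[1]),
            n_cat3=int(counts[2]), n_cat4=int(counts[3]),
            n_cat5=int(counts[4]),
        ))
    return quadrates, fid_trials, predation


# ---------------------------------------------------------------------------
# Genotypes

def _geometric_profile(n_alleles: int, target_h: float = 0.675) -> np.ndarray:
    """Geometric allele-frequency profile p_i ~ q^i with q chosen so the
    expected gene diversity 1 - sum p_i^2 hits ``target_h``; mimics a
    polymorphic microsatellite locus."""

    def h_of(q):
        p = (1.0 - q) * q ** np.arange(n_alleles)
        p /= p.sum()
        return 1.0 - float(np.sum(p * p))

    lo, hi = 1e-6, 1.0 - 1e-6
    if h_of(hi) < target_h:
        raise ValueError("target_h unreachable with this allele count")
    q = optimize.brentq(lambda q: h_of(q) - target_h, lo, hi, xtol=1e-12)
    p = (1.0 - q) * q ** np.arange(n_alleles)
    return p / p.sum()


def simulate_genotypes(scenarios: Sequence[PopulationScenario],
                       n_loci: int = 16, n_alleles: int = 16,
                       seed: int = 0, missing_prob: float = 0.02,
                       target_heterozygosity: float = 0.675,
                       ) -> GenotypeTable:
    """Dirichlet-multinomial island-model genotypes.

    Per locus an ancestral frequency vector is drawn around a geometric
    profile (expected gene diversity ~= ``target_heterozygosity``, the
    study's observed 0.65-0.7 band); each population's frequency vector is
    Dirichlet(theta_divergence * ancestral), or the ancestral vector itself
    when ``theta_divergence`` is None (exact panmixia).  Each individual's
    genotype is two independent allele draws; calls drop out independently
    with probability ``missing_prob``.
    """
    if not scenarios:
        raise ValueError("scenarios must be non-empty")
    if n_loci < 1 or n_alleles < 2:
        raise ValueError("need n_loci >= 1 and n_alleles >= 2")
    rng = _rng(seed, 3)
    profile = _geometric_profile(n_alleles, target_heterozygosity)
    jitter_conc = 200.0

    loci = [f"locus_{j + 1}" for j in range(n_loci)]
    pop_freqs: Dict[str, List[np.ndarray]] = {sc.population: []
                                              for sc in scenarios}
    for _ in range(n_loci):
        ancestral = rng.dirichlet(jitter_conc * profile)
        ancestral = np.clip(ancestral, 1e-12, None)
        ancestral /= ancestral.sum()
        for sc in scenarios:
            if sc.theta_divergence is None:
                pop_freqs[sc.population].append(ancestral)
            else:
                alpha = np.clip(sc.theta_divergence * ancestral, 1e-9, None)
                f = rng.dirichlet(alpha)
                f = np.clip(f, 0.0, None)
                f /= f.sum()
                pop_freqs[sc.population].append(f)

    populations = [sc.population for sc in scenarios]
    individual_pops: List[str] = []
    individual_ids: List[str] = []
    calls: List[List[Optional[Tuple[int, int]]]] = []
    for sc in scenarios:
        n_ind = 2 * sc.n_per_sex  # both sexes genotyped
        for i in range(n_ind):
            row: List[Optional[Tuple[int, int]]] = []
            for j in range(n_loci):
                if rng.random() < missing_prob:
                    row.append(MISSING)
                    continue
                f = pop_freqs[sc.population][j]
                a, b = rng.choice(n_alleles, size=2, p=f)
                row.append((int(a) + 1, int(b) + 1))
            individual_pops.append(sc.population)
            individual_ids.append(f"{sc.population}_g{i:03d}")
            calls.append(row)
    return GenotypeTable(populations, loci, individual_pops, calls,
                         individual_ids)
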