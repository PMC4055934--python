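"""Population-level field indices of sexual and natural selection.

Sexual selection is indexed by the operational sex ratio (adult M:F) and
same-sex competitor density from quadrate censuses; natural selection by
flight initiation distance (FID, in observer paces) and the percentage of
prey models struck by predators.  Ratio and density use two-level averaging:
first over repeat observations within a quadrate, then over quadrates, so
every quadrate carries equal weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np

from .records import FIDTrial, PredationCounts, QuadrateObservation

logger = logging.getLogger("divergekit")

__all__ = [
    "SelectionIndices",
    "population_sex_ratio",
    "competitor_density",
    "flight_initiation_distance",
    "population_fid",
    "percent_predation",
    "compute_selection_indices",
    "MIN_FID_TRIALS",
]

#: Survey protocol targets at least this many FID trials per sex per
#: population; fewer triggers an under-sampling warning.
MIN_FID_TRIALS = 20


@dataclass
class SelectionIndices:
    population: str
    sex_ratio_mf: float
    density_male_m2: float
    density_female_m2: float
    fid_mean_paces_m: float
    fid_mean_paces_f: float
    percent_predation: float


def _two_level_mean(values_by_quadrate: dict) -> float:
    """Mean within each quadrate, then mean across quadrates."""
    quadrate_means = [float(np.mean(v)) for v in values_by_quadrate.values() if v]
    if not quadrate_means:
        raise ValueError("no valid observations")
    return float(np.mean(quadrate_means))


def population_sex_ratio(observations: Iterable[QuadrateObservation]) -> float:
    """Adult male:female ratio, averaged per quadrate then across quadrates.

    Observations with zero females have an undefined ratio and are skipped
    with a logged warning; if none remain the ratio is undefined.
    """
    by_quadrate: dict = {}
    for obs in observations:
        if obs.n_females == 0:
            logger.warning(
                "sex ratio undefined for quadrate %s observation %d "
                "(0 females); skipped", obs.quadrate_id, obs.observation_index)
            continue
        by_quadrate.setdefault(obs.quadrate_id, []).append(
            obs.n_males / obs.n_females)
    try:
        return _two_level_mean(by_quadrate)
    except ValueError:
        raise ValueError(
            "sex ratio undefined: no observation with females present"
        ) from None


def competitor_density(observations: Iterable[QuadrateObservation],
                       sex: str) -> float:
    """Adult same-sex density (fish per m2 of exposed rock), two-level
    averaged.  Fully submerged observations (exposed area 0) are skipped."""
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    by_quadrate: dict = {}
    for obs in observations:
        if obs.exposed_area_m2 <= 0:
            logger.warning(
                "density undefined for quadrate %s observation %d "
                "(fully submerged); skipped",
                obs.quadrate_id, obs.observation_index)
            continue
        count = obs.n_males if sex == "M" else obs.n_females
        by_quadrate.setdefault(obs.quadrate_id, []).append(
            count / obs.exposed_area_m2)
    try:
        return _two_level_mean(by_quadrate)
    except ValueError:
        raise ValueError(
            "density undefined: every observation fully submerged"
        ) from None


def flight_initiation_distance(trial: FIDTrial) -> int:
    """FID = D_start - D_flee, in paces.  Larger = more fearful."""
    return trial.d_start_paces - trial.d_flee_paces


def population_fid(trials: Iterable[FIDTrial], sex: str) -> float:
    """Mean FID over one sex's trials; warns below the protocol's 20-trial
    minimum."""
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    fids: List[int] = [
        flight_initiation_distance(t) for t in trials if t.sex == sex]
    if not fids:
        raise ValueError(f"no FID trials for sex {sex!r}")
    if len(fids) < MIN_FID_TRIALS:
        logger.warning(
            "only %d FID trials for sex %s (protocol targets >= %d)",
            len(fids), sex, MIN_FID_TRIALS)
    return float(np.mean(fids))


def percent_predation(counts: PredationCounts) -> float:
    """100 * N4 / (N1 + N2 + N3 + N4).

    Category 4 (entire portions missing) is the predation signal; category 5
    (anchor only) is excluded from numerator and denominator as probable
    wave or human damage.
    """
    denom = counts.n_cat1 + counts.n_cat2 + counts.n_cat3 + counts.n_cat4
    if denom == 0:
        raise ValueError(
            "%Predation undefined: no stimuli in categories 1-4")
    return 100.0 * counts.n_cat4 / denom


def compute_selection_indices(
    quadrates: Iterable[QuadrateObservation],
    fid_trials: Iterable[FIDTrial],
    predation: Iterable[PredationCounts],
) -> List[SelectionIndices]:
    """Per-population index table from the three survey streams."""
    quadrates = list(quadrates)
    fid_trials = list(fid_trials)
    predation = list(predation)
    pops: List[str] = []
    for rec in quadrates:
        if rec.population not in pops:
            pops.append(rec.population)
    out = []
    for pop in pops:
        q = [o for o in quadrates if o.population == pop]
        f = [t for t in fid_trials if t.population == pop]
        p = [c for c in predation if c.population == pop]
        if len(p) != 1:
            raise ValueError(
                f"expected exactly one predation row for {pop!r}, got {len(p)}")
        out.append(SelectionIndices(
            population=pop,
            sex_ratio_mf=population_sex_ratio(q),
            density_male_m2=competitor_density(q, "M"),
            density_female_m2=competitor_density(q, "F"),
            fid_mean_paces_m=population_fid(f, "M"),
            fid_mean_paces_f=population_fid(f, "F"),
            percent_predation=percent_predation(p[0]),
        ))
    return out
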