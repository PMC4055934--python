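"""Shared record types for the divergence-analysis pipeline.

The pipeline studies phenotypic divergence among populations of a rocky-shore
fish: per-individual morphometrics and colour, quadrate-based demographic
surveys, flight-initiation-distance (FID) trials, plasticine-model predation
scores, and diploid microsatellite genotypes.  Each record type validates its
own invariants at construction so that downstream statistics never see
malformed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "MorphRecord",
    "QuadrateObservation",
    "FIDTrial",
    "PredationCounts",
    "GenotypeTable",
    "AnalysisConfig",
    "ValidationError",
    "MISSING",
    "NOMINAL_QUADRATE_AREA_M2",
]

#: Sentinel for a missing diploid genotype call.
MISSING = None

#: Nominal area of a 50 cm x 50 cm survey quadrate.
NOMINAL_QUADRATE_AREA_M2 = 0.25


class ValidationError(ValueError):
    """Raised when a record violates a documented invariant."""


@dataclass(frozen=True)
class MorphRecord:
    """One photographed fish.

    ``crest_area_mm2`` is the male head-crest area; females lack a crest so
    the field must be ``None`` for sex ``"F"``.  Colour channels are mean
    red/green values (0-255) of the dorsal fin and of a body reference patch,
    already calibrated against a colour standard.
    """

    individual_id: str
    population: str
    sex: str
    body_length_mm: float
    dorsal_area_mm2: float
    ventral_area_mm2: float
    crest_area_mm2: Optional[float] = None
    prop_fin_coloured: Optional[float] = None
    fin_R: Optional[float] = None
    fin_G: Optional[float] = None
    body_R: Optional[float] = None
    body_G: Optional[float] = None
    year: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.body_length_mm > 0:
            raise ValidationError(
                f"body_length_mm must be positive, got {self.body_length_mm}"
            )
        for name in ("dorsal_area_mm2", "ventral_area_mm2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be nonnegative, got {v}")
        if self.sex == "F" and self.crest_area_mm2 is not None:
            raise ValidationError("crest_area_mm2 must be absent for females")
        if self.crest_area_mm2 is not None and self.crest_area_mm2 < 0:
            raise ValidationError(
                f"crest_area_mm2 must be nonnegative, got {self.crest_area_mm2}"
            )
        if self.prop_fin_coloured is not None and not (
            0.0 <= self.prop_fin_coloured <= 1.0
        ):
            raise ValidationError(
                f"prop_fin_coloured must lie in [0, 1], got {self.prop_fin_coloured}"
            )
        for name in ("fin_R", "fin_G", "body_R", "body_G"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 255.0):
                raise ValidationError(f"{name} must lie in [0, 255], got {v}")


@dataclass(frozen=True)
class QuadrateObservation:
    """One census of one quadrate: adult male/female and juvenile counts
    plus the quadrate area not submerged at observation time."""

    population: str
    quadrate_id: str
    observation_index: int
    n_males: int
    n_females: int
    n_juveniles: int
    exposed_area_m2: float

    def __post_init__(self) -> None:
        for name in ("n_males", "n_females", "n_juveniles"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not (0.0 <= self.exposed_area_m2 <= NOMINAL_QUADRATE_AREA_M2 + 1e-12):
            raise ValidationError(
                "exposed_area_m2 must lie in [0, "
                f"{NOMINAL_QUADRATE_AREA_M2}], got {self.exposed_area_m2}"
            )


@dataclass(frozen=True)
class FIDTrial:
    """One flight-initiation-distance trial, distances in observer paces."""

    population: str
    sex: str
    d_start_paces: int
    d_flee_paces: int

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.d_start_paces <= 0:
            raise ValidationError("d_start_paces must be positive")
        if self.d_flee_paces < 0:
            raise ValidationError("d_flee_paces must be nonnegative")
        if self.d_flee_paces > self.d_start_paces:
            raise ValidationError(
                f"d_flee_paces ({self.d_flee_paces}) exceeds d_start_paces "
                f"({self.d_start_paces})"
            )


@dataclass(frozen=True)
class PredationCounts:
    """Damage-category tallies for prey models deployed at one site.

    Categories: 1 no marks, 2 small nicks, 3 large punctures, 4 entire
    portions missing (the predation signal), 5 anchor only (excluded from
    analysis as likely wave/human damage).
    """

    population: str
    n_cat1: int
    n_cat2: int
    n_cat3: int
    n_cat4: int
    n_cat5: int = 0

    def __post_init__(self) -> None:
        for i in range(1, 6):
            if getattr(self, f"n_cat{i}") < 0:
                raise ValidationError(f"n_cat{i} must be nonnegative")


class GenotypeTable:
    """Individuals x loci diploid microsatellite calls.

    ``calls[i][j]`` is an unordered pair ``(a, b)`` of positive integer allele
    codes, or ``None`` for a missing genotype.  ``individual_pops[i]`` names
    the single population individual ``i`` belongs to; ``populations``
    preserves encounter order.
    """

    def __init__(self, populations, loci, individual_pops, calls,
                 individual_ids=None):
        self.populations = list(populations)
        self.loci = list(loci)
        self.individual_pops = list(individual_pops)
        self.calls = [list(row) for row in calls]
        self.individual_ids = (
            list(individual_ids)
            if individual_ids is not None
            else [f"ind_{i}" for i in range(len(self.calls))]
        )
        self._validate()

    def _validate(self) -> None:
        known = set(self.populations)
        if len(known) != len(self.populations):
            raise ValidationError("duplicate population names")
        if len(self.individual_pops) != len(self.calls):
            raise ValidationError("individual_pops and calls length mismatch")
        for i, pop in enumerate(self.individual_pops):
            if pop not in known:
                raise ValidationError(f"individual {i} in unknown population {pop!r}")
        n_loci = len(self.loci)
        for i, row in enumerate(self.calls):
            if len(row) != n_loci:
                raise ValidationError(
                    f"individual {i} has {len(row)} calls, expected {n_loci}"
                )
            for j, call in enumerate(row):
                if call is MISSING:
                    continue
                if len(call) != 2:
                    raise ValidationError(
                        f"call at individual {i}, locus {j} is not diploid: {call!r}"
                    )
                a, b = call
                if a <= 0 or b <= 0:
                    raise ValidationError(
                        f"allele codes must be positive at individual {i}, locus {j}"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.calls)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def shape(self):
        return (self.n_individuals, self.n_loci)

    def population_indices(self, population: str):
        """Row indices of the individuals belonging to *population*."""
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return [
            i for i, p in enumerate(self.individual_pops) if p == population
        ]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented

        def norm(calls):
            return [
                [None if c is None else tuple(sorted(c)) for c in row]
                for row in calls
            ]

        return (
            self.populations == other.populations
            and self.loci == other.loci
            and self.individual_pops == other.individual_pops
            and norm(self.calls) == norm(other.calls)
        )


@dataclass
class AnalysisConfig:
    """Run-wide settings: significance level, resampling effort, the
    allometric-exponent benchmark for sexually selected ornaments, and the
    Jost's D estimator options."""

    alpha: float = 0.05
    n_permutations: int = 10_000
    n_bootstrap: int = 2_000
    rng_seed: int = 0
    exponent_threshold: float = 1.5
    dest_bias_correction: bool = True
    dest_locus_aggregation: str = "arithmetic"
    sex_ratio_as_proportion_male: bool = False
    pace_length_m: float = 0.54
    output_dir: str = "."
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.dest_locus_aggregation not in ("arithmetic", "harmonic"):
            raise ValidationError(
                "dest_locus_aggregation must be 'arithmetic' or 'harmonic'"
            )
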