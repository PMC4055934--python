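"""End-to-end orchestration: simulate -> indices -> PCA -> allometry ->
Jost's D -> model competition -> Mantel follow-up.

The run emits five analysis tables (PCA loadings, allometry coefficients,
pairwise Jost's D, model rankings, Mantel results) plus a manifest recording
the configuration, seed and SHA-256 checksums of every output, so a rerun
with the same seed reproduces the tables byte for byte.  Mantel tests are
run only for traits whose null model is competitive (delta-AICc <= 2): if a
selection index already explains a trait there is nothing for drift to
explain.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .allometry import classify_ornament, sma_fit
from .inference import (
    abs_diff_matrix,
    candidate_models_individual,
    candidate_models_population,
    cohens_d_matrix,
    mantel_test,
    rank_models,
)
from .io import write_report_tables
from .morphometrics import delta_rg, linearize_area, pca_correlation
from .popgen import dest_pairwise
from .records import AnalysisConfig, MorphRecord
from .selection import compute_selection_indices
from .simulate import (
    PopulationScenario,
    default_scenarios,
    simulate_genotypes,
    simulate_morphometrics,
    simulate_surveys,
)

logger = logging.getLogger("divergekit")

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str
    started: str
    finished: str = ""
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record_delta_rg(rec: MorphRecord) -> Optional[float]:
    if None in (rec.fin_R, rec.fin_G, rec.body_R, rec.body_G):
        return None
    return delta_rg(rec.fin_R, rec.fin_G, rec.body_R, rec.body_G)


def _pca_frame(records: Sequence[MorphRecord]) -> pd.DataFrame:
    """Correlation PCA per sex on ln-transformed size traits plus the colour
    characteristics; males carry the head crest (5 variables), females do
    not (4 variables).  Rows with any missing variable are dropped."""
    frames = []
    for sex in ("M", "F"):
        recs = [r for r in records if r.sex == sex]
        variables = ["body_size", "dorsal_fin_area", "prop_coloured",
                     "delta_rg"]
        if sex == "M":
            variables.insert(1, "head_crest_area")
        rows = []
        for r in recs:
            drg = _record_delta_rg(r)
            if drg is None or r.prop_fin_coloured is None:
                continue
            row = {
                "body_size": np.log(r.body_length_mm),
                "dorsal_fin_area": linearize_area(r.dorsal_area_mm2),
                "prop_coloured": r.prop_fin_coloured,
                "delta_rg": drg,
            }
            if sex == "M":
                if r.crest_area_mm2 is None or r.crest_area_mm2 <= 0:
                    continue
                row["head_crest_area"] = linearize_area(r.crest_area_mm2)
            rows.append(row)
        if len(rows) < 2:
            continue
        X = np.array([[row[v] for v in variables] for row in rows])
        res = pca_correlation(X, variables)
        for i, v in enumerate(variables):
            out = {"sex": sex, "row": v}
            for k in range(len(variables)):
                out[f"PC{k + 1}"] = res.loadings[i, k]
            frames.append(out)
        ev = {"sex": sex, "row": "eigenvalue"}
        cp = {"sex": sex, "row": "cumulative_pct"}
        for k in range(len(variables)):
            ev[f"PC{k + 1}"] = res.eigenvalues[k]
            cp[f"PC{k + 1}"] = res.cumulative_pct[k]
        frames.extend([ev, cp])
    return pd.DataFrame(frames)


def _allometry_fits(records: Sequence[MorphRecord], config: AnalysisConfig,
                    rng: np.random.Generator):
    """SMA fits for every trait x population x sex, centred on the per-sex
    grand-mean ln body length, with control-region classification."""
    populations: List[str] = []
    for r in records:
        if r.population not in populations:
            populations.append(r.population)
    fits = {}
    rows = []
    for sex in ("M", "F"):
        sex_recs = [r for r in records if r.sex == sex]
        grand_mean = float(np.mean(
            [np.log(r.body_length_mm) for r in sex_recs]))
        traits = ["crest", "dorsal", "ventral"] if sex == "M" else \
                 ["dorsal", "ventral"]
        for pop in populations:
            pop_recs = [r for r in sex_recs if r.population == pop]
            for trait in traits:
                attr = {"crest": "crest_area_mm2",
                        "dorsal": "dorsal_area_mm2",
                        "ventral": "ventral_area_mm2"}[trait]
                pairs = [
                    (np.log(r.body_length_mm), linearize_area(getattr(r, attr)))
                    for r in pop_recs
                    if getattr(r, attr) is not None and getattr(r, attr) > 0
                ]
                x = np.array([p[0] for p in pairs])
                y = np.array([p[1] for p in pairs])
                fit = sma_fit(
                    x, y, grand_mean, trait=trait, population=pop, sex=sex,
                    alpha=config.alpha, n_bootstrap=config.n_bootstrap,
                    rng=rng)
                fits[(trait, pop, sex)] = fit
        for pop in populations:
            control = fits[("ventral", pop, sex)]
            for trait in traits:
                fit = fits[(trait, pop, sex)]
                cls = ("control" if trait == "ventral" else
                       classify_ornament(fit, control,
                                         config.exponent_threshold))
                rows.append({
                    "population": pop, "sex": sex, "trait": trait,
                    "n": fit.n,
                    "elevation_a": fit.elevation_a,
                    "a_lo": fit.a_ci[0], "a_hi": fit.a_ci[1],
                    "exponent_b": fit.exponent_b,
                    "b_lo": fit.b_ci[0], "b_hi": fit.b_ci[1],
                    "r": fit.r, "classification": cls,
                })
    return fits, pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig,
                 scenarios: Optional[Sequence[PopulationScenario]] = None,
                 out_dir=None) -> RunManifest:
    """Run the full analysis on simulated data and write the table suite.

    Returns the manifest; raises on any stage failure with the stage named.
    """
    started = datetime.now(timezone.utc).isoformat()
    if scenarios is None:
        scenarios = default_scenarios()
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    seed = int(config.rng_seed)

    logger.info("stage simulate: %d scenarios, seed %d", len(scenarios), seed)
    morph = simulate_morphometrics(scenarios, seed)
    quadrates, fid_trials, predation = simulate_surveys(scenarios, seed)
    genotypes = simulate_genotypes(scenarios, seed=seed)

    logger.info("stage indices: %d quadrate observations, %d FID trials",
                len(quadrates), len(fid_trials))
    indices = compute_selection_indices(quadrates, fid_trials, predation)

    def sex_indices(sex: str) -> Dict[str, Dict[str, float]]:
        out = {}
        for ix in indices:
            out[ix.population] = {
                "sex_ratio": ix.sex_ratio_mf,
                "total_density": ix.density_male_m2 + ix.density_female_m2,
                "predator_strikes": ix.percent_predation,
                "intrasexual_density": (ix.density_male_m2 if sex == "M"
                                        else ix.density_female_m2),
                "flight_distance": (ix.fid_mean_paces_m if sex == "M"
                                    else ix.fid_mean_paces_f),
            }
        return out

    logger.info("stage pca")
    pca_table = _pca_frame(morph)

    logger.info("stage allometry")
    boot_rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    fits, allometry_table = _allometry_fits(morph, config, boot_rng)

    logger.info("stage dest")
    dest = dest_pairwise(genotypes, correction=config.dest_bias_correction,
                         aggregation=config.dest_locus_aggregation)

    logger.info("stage models")
    ranking_rows = []
    mantel_rows = []
    pops = dest.populations

    def individual_trait(sex, name, values_by_ind):
        """Rank the 12-model set; Mantel follow-up if Null is supported."""
        y, groups, by_pop = [], [], {}
        for pop, vals in values_by_ind.items():
            y.extend(vals)
            groups.extend([pop] * len(vals))
            by_pop[pop] = vals
        ranking = rank_models(candidate_models_individual(
            np.array(y), np.array(groups), sex_indices(sex)))
        frame = ranking.to_frame()
        frame.insert(0, "trait", name)
        frame.insert(1, "sex", sex)
        ranking_rows.append(frame)
        if ranking.null_supported():
            pops_d, mat = cohens_d_matrix({p: by_pop[p] for p in pops})
            res = mantel_test(mat, dest.values, config.n_permutations,
                              seed=seed)
            mantel_rows.append(_mantel_row(name, sex, res))

    def population_trait(sex, name, value_by_pop):
        ranking = rank_models(candidate_models_population(
            value_by_pop, sex_indices(sex)))
        frame = ranking.to_frame()
        frame.insert(0, "trait", name)
        frame.insert(1, "sex", sex)
        ranking_rows.append(frame)
        if ranking.null_supported():
            _, mat = abs_diff_matrix({p: value_by_pop[p] for p in pops})
            res = mantel_test(mat, dest.values, config.n_permutations,
                              seed=seed)
            mantel_rows.append(_mantel_row(name, sex, res))

    for sex in ("M", "F"):
        by_pop = {
            pop: [np.log(r.body_length_mm) for r in morph
                  if r.sex == sex and r.population == pop]
            for pop in pops
        }
        individual_trait(sex, "body_size", by_pop)
    for sex in ("M", "F"):
        by_pop = {}
        for pop in pops:
            vals = [
                _record_delta_rg(r) for r in morph
                if r.sex == sex and r.population == pop
                and _record_delta_rg(r) is not None
            ]
            by_pop[pop] = vals
        individual_trait(sex, "delta_rg", by_pop)
    population_trait(
        "M", "crest_exponent",
        {pop: fits[("crest", pop, "M")].exponent_b for pop in pops})
    population_trait(
        "M", "crest_elevation",
        {pop: fits[("crest", pop, "M")].elevation_a for pop in pops})

    results = {
        "pca_loadings": pca_table,
        "allometry": allometry_table,
        "dest": dest.to_frame(),
        "model_ranking": pd.concat(ranking_rows, ignore_index=True),
        "mantel": pd.DataFrame(
            mantel_rows or [],
            columns=["trait", "sex", "r", "p", "n_permutations",
                     "exhaustive", "beta_intercept", "beta_intercept_lo",
                     "beta_intercept_hi", "beta_dest", "beta_dest_lo",
                     "beta_dest_hi"]),
    }
    written = write_report_tables(results, out_dir, config=config, seed=seed)
    manifest = RunManifest(
        seed=seed,
        config=vars(config).copy(),
        version=__version__,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        outputs={p.name: _sha256(p) for p in written
                 if p.name != "manifest.yaml"},
    )
    import yaml

    with (out_dir / "run_manifest.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(vars(manifest), fh, sort_keys=True)
    return manifest


def _mantel_row(trait, sex, res):
    return {
        "trait": trait, "sex": sex, "r": res.r, "p": res.p,
        "n_permutations": res.n_permutations_used,
        "exhaustive": res.exhaustive,
        "beta_intercept": res.beta_intercept,
        "beta_intercept_lo": res.beta_intercept_ci[0],
        "beta_intercept_hi": res.beta_intercept_ci[1],
        "beta_dest": res.beta_slope,
        "beta_dest_lo": res.beta_slope_ci[0],
        "beta_dest_hi": res.beta_slope_ci[1],
    }
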