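# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Allometry

Trait areas are linearized as ln √area = ½ ln(area) so every characteristic
shares body length's log-linear scale, and the power law y = a·x^b becomes
a straight line with slope b.  Fits use the standardized (reduced) major
axis: b = sign(r)·s_y/s_x, which treats measurement error symmetrically in
both variables — appropriate because body length and trait size are both
measured, neither controlled.  Body size is centred on the **per-sex grand
mean across all populations** before the elevation is read off; without
centring, elevation and exponent estimates are artefactually negatively
correlated and elevations are not comparable across populations.  Analyses
are sex-stratified throughout, so the grand mean is computed within sex.

Slope confidence intervals use the classical Jolicoeur/Pitman form:
B = t²(α/2, n−2)·(1−r²)/(n−2), bounds b·(√(B+1) ∓ √B), returned sorted so
the interval always contains b (the raw formula reverses for b < 0).  No
analytic elevation CI is uniquely standard for SMA with grand-mean
centring, so elevations carry a seeded percentile bootstrap
(B = 2000 by default); degenerate resamples (zero variance, r = 0) are
redrawn.  r = 0 exactly is an error rather than an arbitrary sign choice,
because the SMA slope's sign is undefined there.

A trait is classified against a control (the ventral fin, hidden from
conspecifics and hence not sexually selected) as:

* **sexually-selected signature** — exponent ≥ 1.5 (inclusive boundary,
  documented) and 95% CIs disjoint from the control's;
* **indistinguishable from control** — exponent ≥ 1.5 but CIs overlap;
* **below threshold** — exponent < 1.5 regardless of overlap.

Sex dimorphism in elevation uses the same CI-separation rule.

## Selection indices

Sex ratio and density use two-level averaging — mean over the repeat
observations of a quadrate, then mean over quadrates — so each quadrate
carries equal weight regardless of how many of its observations were
usable.  Observations with zero females (ratio undefined) or zero exposed
area (fully submerged) are skipped with a logged warning, never pooled or
imputed; if nothing remains the index is an error.  FID is reported in
paces (the field unit); a pace-to-metre constant (0.54 m, from the
13-pace ≈ 7 m protocol) sits in the configuration for conversions.
%Predation uses categories 1–4 only; category 5 (anchor only) is excluded
from numerator and denominator as probable wave or human damage, so the
statistic is invariant to its count.  Juveniles are recorded but enter no
index.  The sex ratio is carried as M:F; a proportion-male transform flag
exists in the configuration for model fitting.

## Jost's D

Per locus and population pair, with typed-diploid counts n₁, n₂ and
harmonic mean ñ:

    H_S* = (2ñ/(2ñ−1)) · (1 − mean of the two Σp²)
    H_T* = (1 − Σ p̄²) + H_S*/(2·ñ·2),  p̄ = unweighted mean frequency vector
    D    = ((H_T* − H_S*)/(1 − H_S*)) · 2

The plug-in (uncorrected) version omits both correction terms and is
bounded in [0, 1]; the corrected version is unbiased near zero and may go
slightly negative — that is information, not an error, and is preserved.
Loci are combined by the arithmetic mean of per-locus D by default.  The
harmonic-mean option (common in microsatellite software) is guarded:
non-positive per-locus values are floored at zero and a zero forces the
aggregate to zero, because the harmonic mean is undefined at 0 — which
near-panmictic data hit constantly.  Missing genotypes are excluded per
locus, not per individual.  Hardy–Weinberg screening is out of scope; a
typed-count report per population × locus supports manual locus vetting.

At the study's sample sizes (34 diploids/population, 16 loci) the
corrected estimator's per-pair sampling standard deviation is ≈ 0.006, so
single-run pairwise values under exact panmixia scatter to ±0.015.  Tests
of the panmictic regime therefore average each pair across 8 replicate
simulations (Monte Carlo sd ≈ 0.002) before asserting the near-zero band.

## Model competition

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).  **k counts every estimated parameter**:
fixed effects plus the residual variance, plus the random-intercept
variance for mixed fits.  This makes AICc values auditable but also means
a single-predictor population-level regression at n = 5 carries a
24-unit small-sample penalty — rankings here are not comparable to
software that counts regression coefficients only.

Individual-level traits (ln body length, ΔR/G) use a Gaussian
random-intercept model y = Xβ + u_pop + ε fitted by **full ML** (not REML,
which would invalidate AICc comparisons across fixed-effect sets).  The
variance ratio λ = σ²_u/σ²_ε is profiled: for fixed λ, β and σ²_ε have
closed forms via block-wise Sherman–Morrison, and ln λ is optimized by
bounded 1-D search on [−30, 15] with tolerance 1e-8, with the λ → 0 (OLS)
boundary checked explicitly.  The fit matches statsmodels' MixedLM (ML) to
~1e-6 in log-likelihood and collapses exactly onto OLS when the sample
between-group variance is zero.

The candidate set mirrors the study design: Null, each single index (sex
ratio, intrasexual density, total density, flight distance, predator
strikes), and each sexual × natural pair — 12 models.  Head-crest
allometric coefficients, being population-level and invisible to
predators at a distance, compete only {Null, sex ratio, intrasexual
density, total density} by OLS across populations.  Effect sizes are
r = t/√(t²+df) with df = (groups − fixed effects) for group-level
predictors in mixed fits and (n − p) for OLS; the sign follows the
coefficient.

A known property of this design, measured here: with nested pair models
sitting ~2.1 AICc units behind the generating single-index model, each
pair overtakes it with probability ≈ P(χ²₁ > 2.1) ≈ 0.15, capping
strict best-model recovery near 72% even for a deterministic effect.  The
robust diagnostic is that the top model *implicates* the generating index
(≥ 90% in tests) and the generating single model stays AICc-viable.

## Distances and the Mantel test

Phenotypic distance between populations is Cohen's d,
|m_i − m_j|/s_pooled with the (n−1)-weighted pooled SD, for
individual-level traits.  Allometric coefficients have no
within-population SD, so coefficient traits use |Δcoefficient| — a
documented departure flagged in output, not a silent substitution.

Mantel r is the Pearson correlation over upper-triangle pairs.  The null
distribution shuffles the phenotypic matrix's rows and columns together.
With ≤ 7 populations all n! relabelings are enumerated, giving an exact
test (p = k/n!); otherwise p = (#{|r*| ≥ |r|} + 1)/(B + 1) from seeded
random shuffles.  Tails are two-sided on |r|, with a 1e-12 tie tolerance.
Regression betas of phenotypic on genetic distance are OLS over the pairs
with t-based 95% CIs; pairs sharing a population are not independent, so
these CIs are descriptive only.  Mantel tests run only for traits whose
null model has ΔAICc ≤ 2: if a selection index already explains the trait,
there is nothing left for drift to explain.

## Synthetic-data model

The generator emulates the study conditions stream by stream; defaults are
fixed once and are the conditions under which all recovery tests run.

* **Morphometrics** — ln body length ~ N(ln 60 mm, 0.15); each trait
  satisfies ln √area = a + b·(ln L − μ_lnL) + N(0, σ) with σ = 0.05, i.e.
  multiplicative noise on the sqrt-area scale, so the ln–ln model is
  exactly linear with Gaussian error and SMA recovery is analytic (exact
  at σ = 0).  Colour channels are drawn directly as calibrated (R, G)
  means; image calibration is not modelled.  25 fish per sex per
  population (the study's per-population minimum).
* **Surveys** — 8 quadrates × 9 observations (the field protocol).
  Counts are Poisson, but the male mean is calibrated by 1-D root-finding
  so that E[M/F | F>0] equals the target sex ratio — a raw μ_m/μ_f choice
  would leave the per-observation ratio index biased upward by
  μ_m·(E[1/F|F>0] − 1/μ_f) — while the total mean matches the density
  target (16 adults/m² by default, a stylised high-density shore; the
  study reports no numbers).  FID trials start at 12–13 paces with
  Poisson(mean 5) flight distances censored at the start distance.
  Damage categories are multinomial with P(cat 4 | not cat 5) equal to
  the strike probability, so E[%Predation] = 100·strike_prob exactly.
* **Genotypes** — 16 loci × 16 alleles.  Ancestral frequencies follow a
  geometric profile with decay chosen so expected gene diversity is
  0.675 (the study's 0.65–0.7 polymorphism band), jittered by a
  concentrated Dirichlet.  Population frequencies are
  Dirichlet(θ·ancestral): θ = 1000 by default (near-panmixia, the
  regime observed), θ = None bypasses perturbation entirely, and smaller
  θ increases differentiation monotonically.  Genotypes are two
  independent allele draws per individual; calls drop out at 2%.
  No linkage, mutation, or coalescent structure is modelled — the
  Dirichlet-multinomial island sketch is sufficient for differentiation-
  estimator tests, and nothing more.

One global seed is split per generator via SeedSequence sub-keys
(1 morphometrics, 2 surveys, 3 genotypes, 4 bootstrap), so each stage is
individually reproducible.  What passing tests show is therefore that the
estimators recover known truth under an idealized version of the field
design; they do not validate the field protocols themselves, nor cover
real-data pathologies such as allele dropout bias, observer variation in
pace length, or non-Poisson clustering of fish.

## Numerical and formatting choices

Report tables round half away from zero at documented precision (with an
8-guard-digit pre-round so binary representation noise cannot flip a
decimal tie).  The pairwise-D table is upper-triangular with a zero
diagonal.  Reruns with the same seed reproduce every CSV byte for byte;
the run manifest records config, seed, version, and SHA-256 checksums of
all outputs (the manifest itself carries timestamps and is excluded from
the byte-identity contract).  Problem sizes in the test and acceptance
suites (e.g. 100-replicate model recovery, 1000-simulation Mantel
calibration, 8-replicate panmixia averaging) were chosen to give Monte
Carlo error comfortably below each asserted tolerance.

## Known limitations

* Elevation CIs are bootstrap percentiles; no analytic alternative is
  offered.
* The mixed model supports a single random intercept only — the study's
  design — not crossed or nested random effects.
* G_ST is available for contrast, but no other differentiation estimators.
* Mantel beta CIs ignore pair non-independence (flagged above).
* Per-population PCA replication exists as a configuration pathway only;
  the primary PCA pools populations within sex.
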