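# divergekit

Quantitative toolkit for asking how populations of one species diverge in
reproductively important traits despite gene flow — and whether sexual
selection, natural selection, or neutral drift is responsible.  The design
follows field studies of the Pacific leaping blenny (*Alticus arnoldorum*),
a land fish whose island populations differ in male ornaments (a head crest
and a red dorsal fin) while microsatellites show almost no genetic
structure, but every component is generic.

## What it computes

**Ornament allometry.**  For a trait of size *y* on body size *x*, the power
law *y* = *a·x^b* becomes linear on the ln–ln scale (areas are first
linearized as ln √area).  Slopes are fitted by standardized (reduced) major
axis regression, *b* = sign(r)·s_y/s_x, with body size centred on the
per-sex grand mean so the elevation *a* is comparable across populations.
Slope CIs use the classical Jolicoeur/Pitman formula; elevation CIs a seeded
percentile bootstrap.  A trait is classified as carrying a
sexually-selected signature when *b* ≥ 1.5 **and** its 95% CI does not
overlap that of a non-ornament control trait (the ventral fin).

**Selection indices.**  Operational sex ratio (adult M:F) and same-sex
competitor density from repeated quadrate censuses (averaged within, then
across quadrates); flight initiation distance FID = D_start − D_flee in
observer paces; and %Predation = 100·N₄/(N₁+N₂+N₃+N₄) from damage
categories of deployed prey models (category 5, anchor-only, is excluded).

**Genetic differentiation.**  Jost's D per locus for each population pair,

    D = ((H_T − H_S) / (1 − H_S)) · n/(n−1),  n = 2 demes,

with Nei & Chesser-style small-sample corrections (harmonic-mean sample
size), read from Genepop files and aggregated across loci by arithmetic
mean (harmonic optional).

**Model competition.**  Candidate models linking population phenotypes to
the selection indices are compared by AICc and Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2); individual-level traits use a
random-intercept Gaussian model fitted by full ML with the variance ratio
profiled by 1-D search, population-level traits (allometric coefficients)
use OLS.  Effect sizes are r = t/√(t² + df).

**Mantel tests.**  When the null model is competitive (ΔAICc ≤ 2), pairwise
phenotypic distance (Cohen's d, or |Δcoefficient| for population-level
coefficients) is tested against Jost's D by permutation; for ≤ 7
populations all n! relabelings are enumerated exactly.

**Synthetic data.**  A generator reproduces all five input streams with
known ground truth: log-normal allometry with multiplicative noise,
Poisson quadrate counts calibrated so the two-level indices are unbiased
for their targets, censored-Poisson FID trials, multinomial damage
categories, and Dirichlet-multinomial island-model genotypes with a
tunable divergence parameter.

## Worked example

```python
import numpy as np
from divergekit import (simulate_morphometrics, simulate_genotypes,
                        sma_fit, classify_ornament, dest_pairwise,
                        linearize_area)
from divergekit.simulate import default_scenarios

scenarios = default_scenarios()
records = simulate_morphometrics(scenarios, seed=42)
males = [r for r in records if r.sex == "M" and r.population == "Pop4"]
x = np.array([np.log(r.body_length_mm) for r in males])
grand = np.mean([np.log(r.body_length_mm)
                 for r in records if r.sex == "M"])
crest = sma_fit(x, np.array([linearize_area(r.crest_area_mm2)
                             for r in males]), grand)
ventral = sma_fit(x, np.array([linearize_area(r.ventral_area_mm2)
                               for r in males]), grand)
print(f"crest:   b = {crest.exponent_b:.2f} "
      f"(95% CI {crest.b_ci[0]:.2f}, {crest.b_ci[1]:.2f})")
print(f"ventral: b = {ventral.exponent_b:.2f} "
      f"(95% CI {ventral.b_ci[0]:.2f}, {ventral.b_ci[1]:.2f})")
print("classification:", classify_ornament(crest, ventral))
d = dest_pairwise(simulate_genotypes(scenarios, seed=42))
print(f"mean pairwise D_est = "
      f"{d.values[np.triu_indices(5, 1)].mean():.5f}")
```

prints

```
crest:   b = 2.64 (95% CI 2.46, 2.82)
ventral: b = 1.46 (95% CI 1.29, 1.65)
classification: sexually-selected signature
mean pairwise D_est = 0.00520
```

The crest exponent exceeds 1.5 and its CI clears the ventral-fin control,
the signature expected of an ornament under sexual selection, while the
near-zero Jost's D says these populations exchange genes freely — so the
ornament difference cannot be drift.

The same stages run from a shell:

```sh
divergekit run --seed 1 --out results/       # full pipeline, 5 tables
divergekit simulate --seed 1 --out data/     # 4 CSVs + Genepop
divergekit dest --genepop data/genotypes.gen --out dest.csv
```

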