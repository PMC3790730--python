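# dogblup

Pedigree-based genetic evaluation of canine hip and elbow dysplasia
scores: a bivariate linear mixed "animal" model with AI-REML variance
components, BLUP breeding values with accuracies, inbreeding and genetic-
trend analysis, and a calibrated synthetic-registry generator.

## Who this is for

Quantitative geneticists and registry analysts who want a tested,
reproducible pipeline for ordinal joint-conformation scores of the kind
collected by voluntary orthopedic registries (hip grades 1–7, excellent
through severe dysplasia; elbow grades 1–4, normal through degenerative
joint disease grade III; lower is better).  Voluntary reporting is
heavily biased against poor scores, and raw score trends are further
confounded by age, sex, breed and era effects — so selection decisions
should rest on estimated breeding values (EBVs) from a mixed model that
adjusts those factors and links generations through the pedigree, not on
raw phenotypes.

## The model

For hip (1) and elbow (2) scores jointly:

    y_k = X_k b_k + Z_k a_k + W_k u_k + e_k,      k = 1, 2

with fixed effects b_k (breed, sex, test-year period, test year nested in
period, birth year, age group; the elbow sub-model omits the period),
additive genetic effects a ~ (0, G0 ⊗ A) on a numerator relationship
matrix A that is block diagonal by breed, independent test-year×month
effects u_k, and residuals with 2×2 covariance R0 for dogs scored on both
joints.  Heritability is h² = σ²_a/(σ²_a + σ²_u + σ²_e); EBV accuracy is
r = √(1 − PEV/σ²_a) with PEV the prediction error variance from the
inverse of the mixed-model equations.  Components are estimated by
average-information REML with exact traces from a block selected inverse
(see `docs/methods.md`).

## Worked example

```python
from dogblup import (SimConfig, published_components, heritability,
                     genetic_correlation, threshold_cutoff,
                     shifted_incidence, simulate_registry,
                     ainverse_sparse, build_design, assemble_mme,
                     solve_mme, evaluate)
from dogblup.experiments import edited_datasets
from dogblup.registry import EditConfig
from dogblup.reml import estimate_components
from dogblup.trends import genetic_trend

# reference bivariate components (published scale)
vc = published_components()
print(f"h2(hip)   = {heritability(vc, 'hip'):.4f}")
print(f"h2(elbow) = {heritability(vc, 'elbow'):.4f}")
rg, re = genetic_correlation(vc)
print(f"r_g = {rg:.4f}, r_e = {re:.4f}")
cut = threshold_cutoff(mean=2.05, sd=0.63, incidence=0.0083)
print(f"liability cutoff = {cut:.2f}")
print(f"incidence after -0.1 shift = {100*shifted_incidence(3.56, 1.95, 0.63):.2f}%")

# a small synthetic registry, estimated from scratch
cfg = SimConfig.recovery(n_breeds=2, dogs_per_breed=800, generations=6, seed=3)
records, pedigree = simulate_registry(cfg, seed=3)
datasets = edited_datasets(records, EditConfig(min_breed_records=1))
rel = ainverse_sparse(pedigree)
design = build_design(datasets, pedigree)
fit = estimate_components(design=design, relationship=rel)
print(f"REML converged in {fit.iterations} iterations; "
      f"h2(hip) = {heritability(fit.components, 'hip'):.3f}")
system = assemble_mme(design, rel, fit.components)
result = evaluate(system, solve_mme(system))
hip = result.for_trait("hip")
trend = genetic_trend(hip["ebv"], hip["birth_year"], hip["breed"], trait="hip")
print(f"pooled AGI = {trend['pooled'].agi:+.5f} EBV units/year")
```

prints

```
h2(hip)   = 0.2273
h2(elbow) = 0.1611
r_g = 0.1240, r_e = 0.0818
liability cutoff = 3.56
incidence after -0.1 shift = 0.53%
REML converged in 4 iterations; h2(hip) = 0.222
pooled AGI = +0.00025 EBV units/year
```

The first block reproduces the headline genetic parameters from the
reference variance components: hip scores are moderately heritable
(h² ≈ 0.23), elbow scores less so (≈ 0.16), and the two are only weakly
genetically correlated (r_g ≈ 0.12) — selecting on hips alone barely
improves elbows.  The liability-threshold lines translate an observed
0.83% dysplasia incidence into a normal-distribution cutoff of 3.56 and
show that improving the mean hip score by 0.1 would cut the incidence to
about 0.5%.  The second block simulates a small two-breed registry on the
Gaussian (liability) scale, re-estimates the variance components from
scratch, evaluates EBVs with accuracies, and regresses the mean EBV on
birth year; under random mating the annual genetic improvement (AGI) is
near zero, as it should be.

## Command line

A thin CLI wraps the pipeline:

```
dogblup simulate --config scenario.yaml --seed 1 --out run/
dogblup evaluate --registry run/registry.csv --pedigree run/pedigree.csv --out run/
dogblup trends   --ebv run/ebv.csv --trait hip
dogblup report   --bundle run/
```

`evaluate` writes `components.json` (G0/U0/R0, h², correlations, SEs),
`ebv.csv` (per dog per trait: EBV, PEV, accuracy, inbreeding F),
per-trait trend tables and an edit-audit log; `report` renders the
variance-component and per-breed AGI summary tables.

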