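# Methods

`dogblup` re-implements a complete pedigree-based genetic evaluation for
canine hip and elbow conformation scores of the kind run on voluntary
orthopedic registries: data editing, relationship/inbreeding machinery,
restricted-maximum-likelihood variance components, BLUP breeding values
with accuracies, and trend/threshold interpretation, together with a
synthetic registry generator that makes every stage testable without the
(non-redistributable) registry itself.

## The model

Hip scores (ordinal 1–7, 1 = excellent … 7 = severe dysplasia) and elbow
scores (1–4, 1 = normal, 2–4 = degenerative joint disease grades I–III)
are analysed jointly on the linear scale with a bivariate animal model

    y_k = X_k b_k + Z_k a_k + W_k u_k + e_k ,   k = hip, elbow

* **b_k** — fixed effects: breed, sex, test-year period (scoring-strategy
  era), test year nested within period, birth year, and four age groups
  (24 / 25–29 / 30–36 / 37–60 months at scoring).  The elbow sub-model
  omits the period factor.
* **a = (a_hip, a_elbow)** — additive genetic effects with
  var(a) = G0 ⊗ A, where A is the numerator relationship matrix, block
  diagonal by breed (only purebred dogs enter; cross-breed parentage is an
  error).
* **u_k** — test-year × test-month environmental effects,
  var(u_k) = σ²_{u,k} I, independent between traits (no u covariance is
  modelled).
* **e** — residuals with 2×2 covariance R0 for dogs scored on both
  joints; dogs with a single trait contribute through the scalar inverse
  of their trait's residual variance (the standard missing-trait
  treatment).

Lower scores and lower EBVs are better for both traits.

Heritability is h²_k = σ²_{a,k} / (σ²_{a,k} + σ²_{u,k} + σ²_{e,k});
genetic and residual correlations are the usual covariance ratios.  The
reference ("published-scale") components used as generator truth are

    G0 = [[0.08488, 0.00270], [0.00270, 0.00559]]
    U0 = diag(0.00057, 0.00002)
    R0 = [[0.28800, 0.00749], [0.00749, 0.02908]]

giving h² ≈ 0.227 / 0.161 and r_g ≈ 0.124, r_e ≈ 0.082.

## Data editing

The registry edits are applied in a fixed order, each rule logging its
removal count into an audit map whose entries sum to input − output:
exact duplicate rows; excluded (chondrodysplastic) breeds and breeds with
fewer than 1000 hip+elbow records (counted on the combined, unfiltered
records); age at scoring outside 24–60 months (both bounds inclusive,
whole calendar months); birth years outside 1970–2007; test years outside
1974–2009; and, per dog and trait, only the last record by test date is
kept (ties broken by file order, last wins).  Elbow data additionally
drop breeds without score variation or with fewer than ten dysplastic
dogs, and birth years before 1988 are grouped into 1988.  For
dichotomization, hip grades 5–7 are dysplastic, grade 4 (borderline)
belongs to neither class, and elbow grades 2–4 are dysplastic.

The exact boundaries of the four historical scoring-strategy eras are not
public; the edit configuration exposes them (`period_breaks`, default
eras starting 1986 and 2000, matching the release-policy changes in how
score categories were published).

Continuous (liability-scale) registry files written by the simulator are
auto-detected at parse time; score-code validation and the ordinal-only
elbow breed rules are then skipped, with a log note.

## Pedigree, inbreeding, relationships

Pedigree cleaning severs impossible links rather than deleting animals
(ancestors are needed to connect the pedigree): female sires/male dams,
ids used both as sire and dam, parents born in the same year as or after
their offspring, and links participating in parentage cycles.  Parents
referenced only as links become ancestors without records, with sex
inferred from role and breed from the offspring.  Output order is breed-
contiguous and topological.  Individuals with an unknown parent are
founders drawn from a non-inbred, unrelated base population; dogs born
1970–1973 have no traceable pedigree and are founders with F = 0.

Inbreeding uses the Meuwissen–Luo recursion (F_i = A_ii − 1 without
forming A); the dense tabular A is kept as an oracle for tests.  A⁻¹ is
assembled directly from parent links with Mendelian-sampling variances
d_i = ½ − ¼(F_s + F_d) (¾ − ¼F with one known parent), which the test
suite verifies against the dense inverse on random pedigrees.

## Mixed model equations and solvers

Henderson's MME are assembled with per-record residual weights (2×2
R0⁻¹ blocks for dual-scored dogs), G0⁻¹ ⊗ A⁻¹ on the animal block and
diagonal U0⁻¹ terms.  Fixed-effect rank deficiency is handled by
reference-level dropping (the first listed factor, breed, keeps all
levels and plays the per-breed intercept role; nested test years drop the
first year per era) plus a pivoted-Cholesky repair of the fixed-effect
Gram matrix that removes any residual accidental confounding (birth year
vs test year vs age group can collide on small datasets).  Every
structural block stays present in the sparse sum even when its
coefficient is zero, so the sparsity pattern is invariant across
variance-component values — cached symbolic factorizations depend on it.

Systems up to 2000 equations are factored monolithically (SuperLU in
symmetric mode).  Larger systems use a breed-block Schur factorization
(`sparsela`): each breed's animal block is factored by an up-looking
sparse LDL' (elimination-tree symbolic analysis cached across
refactorizations; the fill-reducing permutation is taken once from
SuperLU's minimum-degree analysis), and the shared fixed + year-month
columns are eliminated through a dense Cholesky of their Schur
complement.  On the reference scenario this is roughly an order of
magnitude faster than a monolithic factorization, whose fill explodes on
the mixed sparse/dense pattern.  A Jacobi-preconditioned conjugate
gradient solver is available as an alternative solve path and is tested
against the direct one.

## AI-REML

Variance components maximize the restricted likelihood

    −2 l_R = log|R| + log|G| + log|U| + log|C| + y'Py + const,

evaluated through the factorization (log|A| comes free from the
Mendelian-sampling variances).  Updates are average-information steps:

* the AI matrix is exact — AI_ij = ½ f_i' P f_j with f_i = (∂V/∂θ_i) Py,
  each P-application one solve against the current factorization;
* the quadratic part of the score, Py' f_i, is exact;
* the trace part splits into closed forms for the log|R|, log|G|, log|U|
  derivatives plus tr(C⁻¹ ∂C/∂θ_i).  On block-factored systems that trace
  is computed **exactly** through a Takahashi selected inverse of each
  breed block combined with the low-rank Schur term
  (C⁻¹ = blockdiag(A_blk⁻¹, 0) + W S⁻¹ W'); on small monolithic systems it
  is obtained by central finite differences of log|C| (one factorization
  per perturbation, with a one-sided step when a parameter sits at its
  boundary).  A seeded Hutchinson estimator is kept as an explicit
  option but is not the default anywhere.

Steps are damped: per-parameter changes are capped (80% of the current
value or 20% of the phenotypic scale), a step that would leave the
positive-definite cone is projected back (eigenvalue clipping at 1e-10;
year-month variances floored at 1e-10 of the phenotypic scale), and a
step that decreases the likelihood is halved up to 14 times with a final
scaled-gradient fallback, so accepted likelihoods never decrease.  A
variance pinned at its floor whose score pushes it further down is frozen
out of the Newton system for that iteration (active set).  Convergence is
declared when the largest relative parameter change falls below `tol`
(default 1e-6) on a full, undamped AI step, or when the Newton decrement
shows the remaining likelihood gain is below 1e-4 — a halved step can be
arbitrarily small without being at the optimum, so step size alone is not
trusted.  Standard errors come from the inverse AI matrix; SEs for h²
and the correlations use a first-order delta method on that covariance.

Default initialization assigns 10% / 5% / 85% of each trait's observed
phenotypic variance to the additive, year-month and residual components
with zero covariances.

## Prediction error variance and accuracy

PEV is the animal-block diagonal of C⁻¹ and accuracy is
r = √(1 − PEV/σ²_a), clipped to [0, 1] (an inbred animal without
information has PEV = σ²_a(1+F) > σ²_a; PEV beyond that bound raises, as
it indicates a broken system).  On block-factored systems the diagonal is
read exactly from the selected inverse at any scale; small monolithic
systems solve unit vectors in chunks; a seeded Monte-Carlo diagonal
estimator with reported SE exists as a fallback option.

## Trends, selection intensity, thresholds

The annual genetic improvement (AGI) of a breed is the OLS slope of its
yearly *mean* EBV on birth year (matching how trend lines are plotted;
per-dog weighting is available as an option).  Total change over a window
is slope × span, also expressed as a percentage of the phenotypic SD.
The breeder's equation R = i σ_p h² / L back-calculates realized
selection intensity, with the normal-truncation relationship
i(p) = φ(z_p)/p invertible to a retained proportion.  The liability-
threshold view places a cutoff at mean + sd·Φ⁻¹(1 − incidence) and maps
mean shifts to new incidences; the two functions are exact inverses.
The elbow trend window defaults to birth years 1996–2009 (elbow scoring
started late); when a dataset has too few years inside the window the
pipeline falls back to all years with a logged warning.

## Synthetic registry generator

The generator emulates the statistical structure the analysis assumes —
not radiographs or certification workflow.  Closed purebred populations
are bred over discrete generations (default 4 breeds × 3000 dogs over 8
cohorts, generation interval 4.3 years, founders born 1970–1973);
mating is random, truncation (lowest hip merit retained, criterion = true
breeding value plus residual-sized noise) or rank-assortative.  The
selection criterion is drawn in every scheme so the random streams
align: truncation with proportion 1.0 reproduces random mating exactly.
Breeding values follow a ~ (0, G0 ⊗ A) exactly: founders are drawn from
N(0, G0) and offspring get the parent average plus a Mendelian deviation
with covariance (½ − ¼(F_s+F_d)) G0, with F recomputed per generation.

Records realize y = fixed + a + u + e with one visit per dog (so dual-
scored dogs share a test date), per-trait scoring probabilities (default
0.90 hip / 0.25 elbow, giving a minority of dual-scored dogs), breed /
sex / age / test-year / birth-year effects of configurable magnitude
(elbow sex contrast defaults to 0.0082, males worse), and year-month
effects at the U0 variances.  Ordinal recording discretizes liabilities
through *global* per-trait thresholds solved so that the mixture over
realized breed effects, sexes and age groups hits target category
proportions — the defaults put 0.83% of hip mass in grades 5–7 and 2.08%
of elbow mass in grades 2–4, with means/SDs near the registry's 2.05/0.63
and 1.03/0.19.  Breed differences shift the liability rather than the
thresholds, the simplest structure consistent with a linear analysis.

Era-dependent reporting bias censors records with score- and era-specific
probabilities; the default eras release only normal grades (hip 1–3,
elbow 1) before 2000 and everything afterwards.

Two recording scales are first-class.  `ordinal` is the registry
emulation.  `liability` writes the Gaussian response itself and is the
scale of the parameter-recovery experiment (`SimConfig.recovery()`):
recovering the generating components is a test of the linear-Gaussian
estimation machinery under its own assumptions, and interval-censoring a
scale where ~85% of the mass falls in two or three categories would
distort the realized components for reasons unrelated to the estimator.
Consequently, passing recovery tests validates the estimator, not the
adequacy of a linear model for ordinal registry scores — the analysis
model shares that (deliberate) approximation with the evaluation it
re-implements.  Other known gaps between generator and real registries:
no maternal/litter effects, no overlapping generations, no preferential
reporting by family, and reporting-bias magnitudes are scenario inputs,
not estimates.

## Reference experiments (`dogblup.experiments`)

* **Parameter recovery** — the default scenario above, Gaussian
  recording; AI-REML recovers all eight components within 3 SE (the
  acceptance suite runs this at ~4.5 minutes on one CPU; ~13,000 records,
  ~25,000 equations).
* **Incidence calibration** — 50,000 ordinally scored founders; realized
  dysplasia incidences match the 0.83% / 2.08% targets within binomial
  noise plus a small calibration slack.
* **BLUP calibration** — regression of true on estimated breeding values
  at known components has slope 1 within OLS error.
* **Reporting-bias attenuation** — 20 replicates of a truncation-selected
  population with a realistically high true dysplasia rate (the published
  incidences are *reported* incidences; censoring a sub-1% trait would
  barely bite): era censoring attenuates the estimated genetic trend
  relative to the same estimator on complete records (sign test), and
  leaves it short of the simulated true genetic change — the direction of
  bias the evaluation literature predicts for voluntary registries.

## Numerical choices and limitations

* REML tolerance 1e-6 relative parameter change (not tighter: the
  small-system trace path is finite-difference limited), max 200
  iterations; non-convergence is flagged and returned, not raised.
* Dense-path PEV limit 20,000 equations; block-factored systems are
  exact at any size.
* The tabular A oracle refuses pedigrees beyond a configurable dense
  limit (default 5000).
* Year-month variances can sit at their boundary when the data carry no
  information about them (the elbow u variance is essentially zero);
  estimates and SEs there should be read as boundary values.
* Accuracies use plain σ²_a in the denominator (the conventional printed
  formula), so deeply inbred animals with no information clip to 0.
* All randomness flows from explicit seeds; identical configuration and
  seed give byte-identical registry files.
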