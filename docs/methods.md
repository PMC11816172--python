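# Methods

This note documents the statistical model behind `boargwas`, the
numerical choices made where several were defensible, what the synthetic
data do and do not emulate, and the package's known limitations. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## The repeatability animal model

Each semen record of animal *i* is modeled as

    y = μ + year-season + parity + b_age·age + b_intv·interval
        + a_i + p_i + e

with `a ~ N(0, A σ²_a)`, `p ~ N(0, I σ²_p)` over animals with records,
`e ~ N(0, I σ²_e)`. Year–season and parity are categorical fixed effects
(one reference level dropped per factor; a rank check names confounded
columns); age in months and the days since the previous collection are
covariates, centered before fitting. An animal's first record has no
interval; it receives the covariate mean (zero after centering), which is
the least-informative imputation. Covariates that are constant in a data
set carry no information and are dropped rather than treated as a rank
error.

`A` is built by the tabular method, so the diagonal is `1 + F` and
inbreeding propagates exactly. Its inverse, needed inside REML, is taken
by dense inversion: the pedigrees this package targets are O(10³)
animals, where dense algebra is both exact and fast, and it avoids
maintaining a second (sparse-rules) code path.

### AI-REML

Variance components maximize the restricted likelihood by Newton steps on
the average-information matrix, with all traces and quadratic forms
computed through the mixed-model equations: one Cholesky of the
coefficient matrix (order p + q_animals + q_pe) per iteration, plus three
extra MME solves for the AI working vectors. Steps that would leave the
parameter space are halved up to 10 times; if no acceptable AI step
exists, an EM step (which cannot leave the space) is taken instead.
Components are floored at 1e-8 of the phenotypic variance; convergence is
declared at |Δ logL| < 1e-8; non-convergence after 100 iterations raises
an error carrying the trajectory. Standard errors come from the inverse
AI matrix; SEs for h² and repeatability follow by the delta method.

The REML log-likelihood is computed via the standard MME identity
(log|C| plus degree-of-freedom-weighted component logs plus y'Py), which
makes it directly comparable to a dense-V oracle; the unit tests exploit
this by grid-searching the dense restricted likelihood on a small data
set and checking the REML optimum dominates the grid.

### BLUP, reliability, deregression, weights

EBVs are the additive solutions of the MME at the REML estimates; animals
without records are predicted through A. Reliability is
`REL = 1 − PEV/σ²_a` with PEV from the inverted coefficient matrix, with
no inbreeding adjustment of the denominator (the simplest convention;
alternatives rescale by 1+F).

Deregression follows the VanRaden parent-average decomposition exactly as
printed in the source formulas: daughter equivalents `DE = k·REL/(1−REL)`
with `k = (1−h²)/h²`, `R_i = (DE_i − DE_PA)/DE_i`,
`DEBV = PA + (EBV − PA)/R_i`. Animals whose parent average carries at
least as much information as their own proof (`R_i ≤ 0`) cannot be
deregressed; they are flagged and excluded from the scan, with counts
logged.

The scan weight uses a *different*, unscaled daughter-equivalent
convention (`DE = Rel/(1−Rel)`, no factor k) inside
`Rel_Animal = (DE_DEBV − DE_PA)/(DE_DEBV − DE_PA + 1)` and
`weight = (1−h²)/(c + h²(1−Rel_Animal)/Rel_Animal)`. The two conventions
are deliberately kept as printed in the method this package implements,
despite the apparent inconsistency; reconciling them would change the
weights away from the published procedure. The DEBV reliability feeding
the weight is `(DE_i − DE_PA)/(DE_i − DE_PA + k)`, which reduces to REL
when the parent average is uninformative; setting
`deregress(..., rel_debv_from_rel=True)` switches to plain REL. The
default `c = 0.1` is the share of genetic variance assumed uncaptured by
markers.

## The weighted association scan

The GRM is VanRaden method 1, `G = MM′/(2Σp_j(1−p_j))`, allele
frequencies from the sample, missing dosages mean-imputed, monomorphic
markers excluded, and a 1e-6 ridge on the diagonal. The candidate marker
is *not* removed from G (no leave-one-chromosome-out): the scan follows
the all-markers-G convention of the weighted method it implements, which
costs a little power (proximal contamination) but keeps one fixed null
covariance.

The null model `y = 1μ + g + e`, `Var(y) = Gσ²_g + diag(1/w)σ²_e`, is
whitened by √w and reduced by one eigendecomposition to a 1-D REML
profile over the variance ratio (grid search on log δ ∈ [−12, 12]
followed by bounded Brent refinement). If the profile is flat —
e.g. G = I with equal weights, where the two components are genuinely
unidentifiable — the fit warns and returns an even split of the total
variance. Per-marker tests are then GLS with the covariance fixed at the
null fit (the standard two-step approximation; O(n) per marker), 1-df
Wald p-values. Weights therefore enter both the null REML and the
per-marker GLS.

λ is the median observed 1-df chi-square over 0.4549364. q-values:
Benjamini–Hochberg step-up, optionally (default) rescaled by a Storey
π₀ estimated on the λ-grid 0.05–0.95 with a cubic-polynomial smoother
evaluated at the grid maximum, clipped to (0, 1]; with fewer than 20
p-values π₀ is fixed at 1 (the smoother is meaningless there).
Monotonicity along the p-ranking is enforced. Per-marker explained
genetic variance is `100·2pq·β²/σ²_g`; the formula is a convention (the
source tables do not define theirs), so those printed values are not
treated as reproduction targets.

## Quality control

Record-level phenotype rules, in order: volume ≤ 50 mL removed; motility
< 10% removed; collection interval > 60 days or exactly 0 days removed
(intervals from the records surviving the first two rules; the first
record per animal is exempt). The minimum-collections rule (≥ 5) is
applied last, to post-filter counts — the source wording is ambiguous
about raw versus surviving counts, and this reading is recorded in the QC
report notes. Marker filters run in a fixed order — unmapped, call rate
< 0.9, MAF < 0.01, HWE exact p < 1e-6 — each computed on the markers
surviving the previous filter. The HWE test is the exact conditional
test (no mid-p), two-sided by probability mass. PCA standardizes dosages
by `2p` and `√(2p(1−p))` (monomorphic markers skipped) and uses a
thin SVD; no LD pruning is applied.

## The synthetic data

The generator emulates the covariance structure the model assumes, at
station-realistic defaults: founder haplotypes from a latent Gaussian
AR(1) process with correlation `exp(−d/200 kb)` thresholded at the
per-marker allele frequency (MAF uniform on 0.05–0.5), giving a
realistic MAF spectrum and distance-decaying local LD; offspring by
gamete dropping with Poisson recombination at a uniform 1 cM/Mb, no
interference; true breeding values as optional QTL marker effects
(rescaled to exact variance fractions) plus an infinitesimal pedigree
component with Mendelian-sampling variance reduced for known parents.
Repeated records follow the generative counterpart of the fitting model:
the permanent-environment deviate is drawn once per animal and reused
across its records; record counts are 1 + Poisson; dates advance by 3–14
day gaps so year–season levels emerge from the calendar. Default trait
scales are typical Duroc stud values (e.g. motility 81.25 ± 12.36%,
count 34.97 ± 18.85 billion) with default h² = 0.33 and
permanent-environment share 0.06; percent traits are clipped to [0, 100]
(counts floored at 0.01) and clipping rates are recorded in the truth
set rather than re-drawn, which keeps the moments close to nominal.
Expression is `baseline + effect·dosage + N(0, σ)` for cis-regulated
genes in a single testis-like tissue, pure noise otherwise, shifted
non-negative.

All randomness derives from one root seed through named SeedSequence
children per stage, so identical seeds give bit-identical studies.

What the simulator does **not** emulate: coalescent-exact LD and allele
frequency spectra, selection and non-random mating, multi-breed
admixture, genotype-by-environment interaction, seasonal trait trends,
count-data skewness, and the read-level provenance of expression values.
Passing tests therefore demonstrate correctness of the estimators under
the assumed model, not robustness to real-data violations of it.

A note on test conditions: traits at the real motility scale
(81.25 ± 12.36 on a 0–100 scale) clip a few percent of records at the
upper bound, exactly as real CASA data saturate at 100%. Variance
recovery checks instead use a mid-scale trait (mean 50, same SD), chosen
a priori because REML is translation invariant and the check should
isolate estimator error from boundary censoring.

## Problem sizes

The shipped checks use: 20 replicates of 800 phenotyped animals × ~8
records for variance-component recovery; 400 genotyped animals × 5000
markers for null-scan calibration and the end-to-end determinism run; 25
replicates × 1000 markers for QTL power; exhaustive enumeration of all
pedigrees with ≤ 5 animals (plus sampled 6–8 animal pedigrees) against a
recursive-coancestry oracle; and all genotype tables with ≤ 50
individuals for the HWE exact test. These sizes were chosen so each
check has clear statistical resolution while the whole suite stays
desk-scale.

## Known limitations

- Single-trait analyses only; no multi-trait REML or genetic
  correlations between semen traits.
- Pedigree-based evaluation only (no single-step genomic BLUP).
- The two-step scan covariance is fixed at the null fit; exact per-marker
  REML would be slower and typically changes little.
- EM LD assumes Hardy–Weinberg within the sample when resolving double
  heterozygotes.
- The co-localization report is overlap/LD-based, not a Bayesian
  posterior over shared causal variants.
- Dense linear algebra throughout caps practical pedigree size at a few
  thousand animals — ample for station-scale data, unsuitable for
  national evaluations.
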