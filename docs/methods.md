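# Methods

`phenosel` implements a phenomic-assisted selection workflow for seed yield
in multi-environment breeding trials, together with a synthetic trial
generator that makes every stage testable end to end.  This note documents
the statistical models, the generator's assumptions, the numerical choices,
and what the tests do and do not demonstrate.

## The trial model and BLUP preprocessing

All phenotypes (plot yield, canopy area CA, pass-centered canopy
temperature CT, vegetation indices, binned waveband reflectances) are
analyzed with the alpha-lattice mixed model

    y_ijkl = mu + E_i + R_j(i) + B_k(ij) + G_l + GE_il + eps_ijkl

with environment (E), replicate within environment (R), incomplete block
within replicate (B), genotype (G) and genotype-by-environment (GE) all
random and independent, `eps ~ N(0, sigma_e^2)`.  Two preprocessing routes
feed the prediction models:

* **Method 1 (by environment):** the reduced model
  `y = mu + R + B(R) + G + e` fit within each environment, producing one
  genotype BLUP per environment.  These retain environment-specific
  genotype performance.
* **Method 2 (across environments):** the full model fit once, producing a
  single genotype BLUP.  Unbalanced genotype-environment incidence
  (environments without phenomics) is handled naturally by the mixed-model
  equations.

Exported values are predicted genotype means (`mu + BLUP`).  Observations
with |internally studentized conditional residual| > 3 are dropped once and
the model refit (one pass, no iteration).  A genotype left with no usable
observations for a trait in an environment receives the population
prediction (full shrinkage).

### REML implementation

Estimation works on Henderson's mixed-model equations with the largest
random term (usually GE) absorbed, so each iteration factorizes only the
dense Schur complement over the remaining effects (a few hundred rows even
for thousands of plots).  The restricted log-likelihood comes free from the
same factorization via
`-2 l_R = (n-q-1) log s2e + sum_i q_i log s2_i + log|C| + y'Py`.

The optimizer runs three EM warmup steps and then switches to
average-information (AI) updates.  Every AI proposal is validated against
the restricted likelihood: a proposal that decreases it is halved up to
three times and then abandoned for the (monotone) EM update, with a short
AI cooldown.  Components whose proposal leaves the parameter space are
fixed on the zero boundary and dropped from the AI system; a pinned
component whose score turns positive is released with an interior restart.
Convergence is declared when the component-wise relative change of the EM
map falls below 1e-6 *or* the deviance change falls below 1e-9 relative —
the second rule matters because a variance sitting on its zero boundary
approaches it only harmonically and never satisfies a relative-change
criterion, while the likelihood has long converged.  Plain EM with the
same tolerance is the fallback behavior and gives identical answers on
interior optima; the AI path needs roughly 10-30x fewer iterations, which
is what makes per-waveband repeatability screens (thousands of REML fits
sharing one design) affordable.  Fits agree with `lme4::lmer` to at least
four significant digits in the variance components and to ~1e-3 in the
genotype BLUPs (asserted in the test suite via `Rscript`).

A fixed ridge of `1e-12 * n` on the Schur complement guards the exact
confounding of the intercept with the absorbed indicators when the
absorbed term's shrinkage ratio vanishes.  The ridge is deliberately on
the count scale: anything proportional to the matrix trace destroys the
likelihood cancellation `q log sigma^2 + log|C|` when a component
approaches zero.

## Spectral preprocessing

1. average the two reflectance scans per plot (single scans are used with a
   warning when one is missing);
2. estimate per-waveband repeatability
   `H2 = s2_G / (s2_G + s2_GE/e + s2_eps/(r e))` from the full REML fit;
3. drop bands with `H2 < 0.3`; bands must pass in every growth stage so
   both stages share one retained grid;
4. compute vegetation indices (NDVI, VREI2, NWI, RARSb, RARSc, NMDI, all
   standard literature definitions) from the scan-averaged spectra at the
   nearest measured band — computing them before binning keeps an index
   usable even when repeatability filtering removes one of its bands;
5. average retained bands into contiguous 10-nm blocks anchored at the
   lowest retained wavelength of each contiguous segment, dropping partial
   trailing blocks (1780 retained 1-nm bands yield exactly 178 features,
   labeled by their rounded mean wavelength, e.g. `R705` for 700-709 nm).

Yield preprocessing removes plots whose emergence stand count falls more
than two interquartile ranges below their environment's first quartile
(linear-interpolation quantiles, strict inequality), censors yield from
plots with preharvest shatter score >= 4 (phenomics retained), and rescales
harvested yield to a 13% moisture basis preserving dry matter:
`y13 = y_wet (1 - m) / 0.87`.

## Genomic parameters

Markers are filtered at >10% missingness, mean-imputed, then filtered at
MAF < 5% (mean imputation stands in for haplotype-based imputation, which
is unnecessary below 10% missingness).  The relationship matrix is
`A = WW' / (2 sum p(1-p))` with `W` the 2p-centered dosage matrix.

SNP heritability fits `y = mu + u + e`, `u ~ N(0, A s2_g)`, by exact REML:
rotating by the eigenvectors of `A` diagonalizes the covariance so the
restricted likelihood is O(n) per evaluation, and a bounded scalar search
over `h2 = s2_g/(s2_g+s2_e)` (total variance profiled out) finds the
optimum; the SE comes from the observed information via the delta method.
Genetic correlations use the bivariate extension with unstructured 2x2
genetic and residual covariance matrices, optimized over their Cholesky
factors (Nelder-Mead) in the same rotated space, with a 1e-8 ridge keeping
the matrices positive definite; `rg` is clipped to [-1, 1] with a warning
if optimization steps marginally outside.  Phenotype inputs are the
Method-2 BLUPs.  At a few hundred genotypes the sampling error of `rg` is
substantial (SE ~0.15-0.25); recovery claims are therefore about medians
over replicated simulations, never single fits.

## Prediction, optimization and selection metrics

Random-forest regression (scikit-learn, 500 trees by default,
`min_samples_leaf=2`) maps phenomic predictors to yield BLUPs within four
cohorts: canopy (CA, CT), VI, canopy+VI, and binned wavebands.  Tuning of
the per-split candidate features by repeated k-fold CV is available but off
by default in batch experiments (the default `max_features=0.33` behaves
well across cohorts and the grid search multiplies cost ~50x).  Accuracy is
the Spearman rank correlation between observed and predicted test BLUPs,
computed within test environment and averaged (pooled computation behind a
flag).  Two CV scenarios mirror breeding decisions: CV1 holds out 20% of
accessions in observed environments; CV2 additionally holds out an entire
environment, training only on the other environments.  Method-2 models
train on across-environment BLUPs but are always evaluated against
by-environment BLUPs when those exist, so methods compete on the same
target.  Only environments with complete predictor data participate in
by-environment training/testing; sparse-phenomics environments still
inform the across-environment BLUPs.

The GA selects 4 distinct 10-nm bins (shared across both growth stages, so
4 bins expand to 8 model features out of 178 x 2 = 356 candidates; a
stage-specific mode exists behind a flag).  Settings: population 50,
30 generations, tournament size 3, uniform crossover at 0.8 with repair to
distinctness, per-gene mutation 0.1 to an unused bin, elitism 2, patience
10, fitness = mean Spearman rho over an internal 5-fold split of the
training rows with a reduced 100-tree forest, cached per chromosome.  With
by-environment rows the fitness rho is computed within each test-fold
environment and averaged, matching the final evaluation metric — pooled
ranks would reward environment-level spectral shifts that carry no
genotype-ranking information.  Test rows never reach the fitness function
(the result records the exact training index for audit).  The final multisensor model retrains a
full-size forest on the selected bins plus the VI with the largest |rg|
with yield and the canopy traits.

Selection metrics binarize ranks at a 20% selection intensity:
`k = round(0.2 n)` (minimum 1) genotypes are "selected" under the observed
and the predicted ranking separately (ties broken by genotype identifier),
giving TP/TN/FP/FN and SPE = TN/(TN+FP), FS = 2TP/(2TP+FP+FN),
BAC = (TPR + TNR)/2 — the printed form of the balanced-accuracy equation
in the source material is garbled and is read as standard balanced
accuracy.

## The synthetic trial generator

The generator emulates a 292-accession soybean panel grown in six
environments (two replicates of thirty incomplete blocks each) with
canopy phenomics at two growth stages and ~35k biallelic SNPs.  Genotypes
are Binomial(2, p) draws with p ~ Uniform(0.05, 0.95); yield genetic
values are additive over 200 causal SNPs; plot yield follows the full
trial model above.  Defaults: mean yield 2100 kg/ha, var(E) = 250k,
var(R) = var(B) = 10k, var(GE) = 40k, var(eps) = 90k (kg/ha)^2, and
plot-level heritability `h2_yield = 0.45`, which fixes
`var_G = h2/(1-h2) (var_GE + var_eps)`.

Reflectance is a smooth vegetation-like baseline plus structured
deviations.  Two spectral regions (red edge 700-850 nm, SWIR 2030-2119 nm)
carry genetic signal: at wavelength w with target genetic correlation
rho(w), the genotype deviation is built from the standardized genetic
yield values so the band-yield genetic correlation equals rho(w) by
construction, with independent smooth (Gaussian-bump basis) genetic noise
elsewhere.  Three further mechanisms make the data behave like real canopy
measurements:

* **Performance tracking at every level.**  GxE and environment spectral
  deviations default to scaling with the corresponding yield variance
  components and share the informative-region correlation; canopy traits
  (CA rg 0.33, CT rg -0.44) carry a GxE performance component too.
  Reflectance is a readout of the realized canopy, so a genotype's
  environment-specific performance is visible in its environment-specific
  spectrum — without this, by-environment (Method-1) models could never
  outperform across-environment ones, contrary to how such data behave.
* **A performance-tracking red-edge shift** (3 nm per SD of total
  performance): higher-performing canopies move the reflectance inflection
  to longer wavelengths.  The direct deviation channel's loading on the
  performance axis is compensated so per-band genetic correlations and
  repeatabilities still hit their configured targets exactly; the shift
  only redistributes the correlation across neighboring bands.  This is
  what gives the derivative-type red-edge index VREI2 its predictive
  value, as its strong reported genetic correlation implies it must have.
* **Sparse phenomics coverage**: `n_spectra_environments` limits spectra
  to a subset of environments, reproducing the common situation where
  across-environment BLUPs pool environments that by-environment models
  must exclude.

Plot quality is degraded deliberately (1% low stand counts, 1% shatter
scores >= 4 with a yield penalty, harvest moisture ~N(0.13, 0.015)), SNPs
get ~1% missing calls with 2% of markers at 11-20%, and two scans per plot
carry scan-level noise — so every filter in the pipeline is exercised.
The truth record stores the genetic values, per-band rg and H2, the
generative variance components, and the entry-mean heritability.

What the generator does **not** emulate: radiative-transfer spectral
physics, spatial field trends beyond the block structure, weather, trait
nonlinearities (all channels are linear-Gaussian), linkage disequilibrium
(markers are independent), or population structure.  Tests passing on this
generator therefore demonstrate correctness of the estimators and the
qualitative logic of the pipeline, not real-world accuracy levels.

## Problem sizes used in the tests

Unit and acceptance tests scale the design down to keep the suite fast:
coarse spectral grids (25-100 nm instead of 1 nm), 60-120 genotypes for
pipeline-level checks, reduced forest sizes (50-300 trees) and GA budgets
(population 16-24, 8-10 generations).  Parameter-recovery runs use the
full stated design (300 genotypes x 6 environments x 2 replicates; GRM
recovery at 300 genotypes x 2000 SNPs) with medians over 20 independently
generated replicates.  The trend checks (CV1 vs CV2, Method 1 vs Method 2,
multisensor vs wavebands-only, training-size response) run on a 120 x 6
trial with spectra in four environments and var(GE) = 120k ~ 1.4 var(G) —
the sparse-coverage, strong-interaction regime those trends are about.

## Known limitations

* The AI-REML boundary handling pins variance components at zero rather
  than allowing the negative estimates some ANOVA-style estimators report;
  repeatabilities are therefore never negative.
* Pairwise bivariate REML does not enforce joint positive definiteness
  across many traits; each pair is fit independently.
* The replicate and environment variance components carry very little
  information at the emulated scale (6 and 12 levels); their estimates are
  exact REML but individual-run values scatter widely, which is a property
  of the design, not of the estimator.
* Random-forest OOB R2 can be pessimistic for small training sets; the
  cross-validated Spearman rho is the accuracy measure used for decisions.
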