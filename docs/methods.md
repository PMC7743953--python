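# Methods

## Scope

`equigen` implements the quantitative-genetic analysis chain used to study
whether accelerometric gait traits and judges' scores help select sport
horses for jumping competition: pedigree relationship algebra, animal-model
BLUP and EM-REML with permanent-environment effects and structured
residuals, PCA-based synthesis of gait traits, a GRAMMAR two-step GWAS, a
rank-based annual performance score, and the attenuation of genetic
correlations when scores are residualized on parent-average EBVs.  Because
no raw accelerometric, show or competition data are public, the package
ships a synthetic-population generator that reproduces the statistical
structure these analyses assume, and every method is validated against
that generator by parameter-recovery experiments.

## Pedigree relationship algebra

The numerator relationship matrix A is built by the tabular recursion
(`a_ij = (a_{i,s(j)} + a_{i,d(j)})/2`, `a_ii = 1 + F_i`); its sparse
inverse by Henderson's direct rules with Mendelian-sampling variances
`d_i = 0.5 - 0.25 (F_s + F_d)` (1 for founders, `0.75 - F/4` with one
known parent).  Inbreeding for the inverse is computed without forming A
by Meuwissen & Luo ancestor tracing, so `a_inverse` scales past the dense
range (dense A is intended for up to a few thousand individuals).  Unknown
parents are treated as unrelated base-population founders; `log|A| = sum
log d_i` is reused in the REML likelihood.

## Mixed models

All analyses are cases of the multi-trait animal model
`y = Xb + Za + Zp + e` with `V(a) = G (x) A`, `V(p) = P (x) I` and
per-record residual covariance from the trait sub-block of `R` (records
missing some traits use the corresponding sub-block; trait pairs never
observed on the same record have structurally zero residual covariance).
The zero pattern of `R` can additionally be constrained explicitly, which
is how the structured-equation treatment of height is realized: height
enters the gait-trait models as a covariate, height and the gait traits
live on different records, and their residual covariances are fixed at
exactly zero so the environmental height-gait association is carried
entirely by the regression coefficient.

Henderson's equations are assembled with per-pattern cached
cross-products, so re-weighting under new variance components costs
O(patterns), not O(records).  Systems up to ~6,000 equations are solved by
dense Cholesky; larger ones fall back to Jacobi-preconditioned conjugate
gradients (tolerance 1e-10 relative).

### EM-REML

Variance components are estimated by EM-REML: each step takes the
prediction-error covariance blocks from the inverse coefficient matrix and
updates `G = (A-hat' A^-1 A-hat + tr(A^-1 C^aa))/q` (and analogously P and
R, the residual update running per record pattern with pair-wise
co-observation counts).  Starting values split each trait's sample
variance in thirds across G, P and R.  Plain EM crawls near the optimum,
so each cycle performs two EM steps and a SQUAREM-style squared
extrapolation; the extrapolated candidate is clipped to the PSD cone and
accepted only if it does not lower the restricted likelihood, which keeps
the likelihood trace monotone by construction while cutting the step count
roughly four-fold.  Convergence is declared when the largest scaled
parameter change falls below `tol` (default 1e-6, cap 500 EM steps; the
desk-scale experiments use 1e-5 to 5e-4, which moves heritability
estimates by well under 0.01).  Updates that leave the PSD cone are
clamped by eigenvalue clipping and flagged (`boundary`); standard errors
of components are out of scope (a parametric bootstrap can be layered on
the generator).

The pre-adjustment model for the PCA (an iid horse effect, no pedigree)
has a diagonal random-effect block, so it uses a dedicated Schur-
complement EM (`fit_iid_repeatability`) whose per-iteration cost is
O(fixed-effects^2 x horses).

## Gait PCA

Per-horse summaries are BLUPs of the horse effect for trot and canter
(repeated working/medium records, velocity-within-type covariates) and
fixed-effect-adjusted phenotypes for walk (single record).  PCA is run on
the correlation matrix (measurements are on incommensurate scales, so
standardization is the defensible default; raw-covariance PCA would be
dominated by the high-variance measurements).  Three components are
retained per gait.  Component naming is deterministic — rank, gait letter,
then the measurement with the largest-magnitude loading (e.g. `PCT1_DVD`)
— and each eigenvector is flipped so that its leading loading is positive,
ties broken by column order; eigenvector signs are otherwise arbitrary, so
only this convention (not the sign pattern itself) is testable.  Record-
level PC values (the same linear combination applied to each record's
standardized measurements) feed the animal models and the GWAS.

## GRAMMAR GWAS

The first step fits the polygenic animal model once per trait; the second
regresses the permanent-environment estimates (repeated-record traits) or
the residuals (single-record traits such as height, and the walk
components — the natural choice since no p-hat exists for them) on each
SNP's additive dosage.  Dosages count the minor allele; missing calls are
mean-imputed.  QC keeps SNPs with MAF > 2%, exact-test HWE p > 1e-6 and
call rate > 90%; the HWE test enumerates heterozygote counts conditional
on allele counts in log space.  P-values are raw two-sided t-tests (a
Bonferroni column is emitted for convenience); no genomic control is
applied.  Positions are 1-based.

## Annual performance score

Every starter earns `base^level * exp(scale * E[Z_(rank)])` points, where
`E[Z_(rank)]` is the expected standard-normal order statistic of the rank
among the starters, computed by adaptive quadrature of
`z * k C(n,k) Phi^{k-1} (1-Phi)^{n-k} phi(z)` in log space (absolute
tolerance 1e-8, cached per n; Blom's approximation is available as a fast
fallback).  Points are summed per horse-year and log-transformed.  The
defaults `scale = 1`, `base = 2` are conventions — the exponential
structure, not any federation's actual table.  Tied ranks are rejected at
validation (the event model never produces them).

## Attenuation of genetic correlations

If a score with genetic correlation `r_a` to competition is residualized
on a parent-average EBV of reliability `CD0`, the expected genetic
correlation of the residual trait is `r_a* = r_a (1 - CD0) /
sqrt(1 - r_a^2 CD0)`; with `r_a = 0.40` and `CD0 = 0.312` this gives 0.28.
The closed form is cross-validated against a structural Monte-Carlo
(parents, Mendelian sampling, noisy parental evaluations, OLS
residualization) that shares no code with it.  Residualization itself is
marginal OLS of score on PA (an optional within-show centering could be
added; the marginal reading is what the description of the regression
supports).  Parent-average reliability is `(CD_sire + CD_dam)/4`.

## Synthetic-data generator

The generator defines the study conditions:

* **Pedigree** — discrete generations, polygynous matings (a ~12% male
  subset sires each generation), yielding paternal half-sib families like
  a sport-horse population; defaults: 150 founders, 3 generations of 500,
  1,477 measured and 702 genotyped horses in the last generation.
* **Breeding values** — generation-wise Mendelian sampling: child = parent
  mean + deviation with covariance `d_i G`.  This scales linearly,
  respects inbreeding exactly, and never factorizes `A (x) G`.
* **Trait system** — 20 gait measurements (7 trot, 6 canter — no symmetry
  at canter — 7 walk) plus height, a latent competition trait (h2 0.30,
  annual repeatability 0.52) and an intrinsic judge-score trait (h2 0.25,
  genetically uncorrelated with competition).  Means, SDs and velocities
  follow published descriptive statistics for accelerometric gait testing
  of young jumping horses (e.g. working trot velocity 3.57 +/- 0.43 m/s);
  heritabilities and repeatabilities echo published magnitudes.
  Correlations come from loadings on three latent factors (vertical
  motion, activity, walk-specific), giving PSD covariances by
  construction; residual correlations exist only within a gait, matching
  the record structure.
* **Records** — trot/canter twice (working/medium), walk once; gender,
  age and event fixed effects are drawn once per study (event effects
  uniform over +/-0.5 SD, i.e. a range of about one phenotypic SD, since
  only the order of magnitude is known); velocity acts through a
  standardized regression slope.
* **Genotypes** — founder dosages Binomial(2, f) with f ~ U(0.05, 0.5),
  single-locus gene dropping (no LD), 2% missingness, one QTL on
  chromosome "3" near 105.65 Mb whose allelic effect is scaled to a chosen
  fraction (default 15%) of the height phenotypic variance; the polygenic
  height variance shrinks correspondingly so total h2 is preserved.  The
  QTL acts on height only, so a gait-trait scan after height correction is
  null by construction.
* **Competition** — a per-horse-year latent value (genetic + permanent +
  annual deviation) plus per-start noise orders the starters of each
  randomly assembled event; ranks are therefore exactly the latent order
  when noise is zero.
* **Judges' scores** — intrinsic genetic component plus `k_pa` times the
  standardized parent-average EBV plus noise.  Parental evaluations have
  reliability 0.62 each, so PA reliability is 0.31, matching the mean
  reliability reported for parental jumping evaluations; `k_pa = 1`
  implies a raw score-competition genetic correlation near 0.45, the
  magnitude reported for canter scores.  Setting `k_pa = 0` removes the
  mechanism.

What the generator does **not** emulate: raw 100-Hz acceleration signals,
linkage disequilibrium, selection or assortative mating, breed structure,
judge-specific biases, or censoring of competition careers.  Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated model, not robustness to those real-data
features.

## Experiment designs (desk scale)

The recovery experiments fix designs chosen to finish in minutes on one
CPU while leaving tolerances meaningful: the repeatability recovery uses
40 sires x 10 offspring x 5 records (2,000 records); the bi-trait
recovery 40 x 10 with one working + one medium record; GWAS calibration
700 genotyped offspring of 70 sires with 10,000 null SNPs (and 1,000-SNP
replicates for power); the raw-vs-residual score contrast 220 measured
horses over two generations with three competition years.  The three-trait
analyses run on pedigrees of a few hundred animals rather than the
hundreds of thousands a national evaluation would use; `run_pipeline`
likewise subsamples its REML stages to `max_reml_animals` (default 400).

## Numerical choices and edge cases

* Quadrature tolerance 1e-10 per order statistic; antisymmetry is imposed
  exactly (scores are mirrored, middle entry zero).
* PSD clipping floor: 1e-10 of the largest eigenvalue.
* Monomorphic SNPs after imputation get `beta = NaN`, `p = 1`, flag
  `monomorphic`; an all-SNPs-removed QC result is a warning, not an error.
* Pedigree cycles are reported with an individual on the cycle; duplicate
  ids, duplicate ranks within an event, zero-variance EBV columns and
  constant PCA columns are all rejected with the offending name.
* All randomness flows from one integer seed through
  `numpy.random.Generator.spawn`, so outputs are bit-reproducible for a
  given numpy version.

## Known limitations

* EM-REML gives point estimates only; no asymptotic standard errors.
* The R zero-pattern is enforced by masking the EM update; for trait
  pairs that are genuinely co-observed on a record this is an ECM-style
  approximation (in all shipped analyses the masked pairs are never
  co-observed, so the constraint is exact).
* Dense prediction-error covariances cap REML problems at a few thousand
  equations per fit.
* The GWAS second step is plain OLS on GRAMMAR responses; its effect
  sizes are conservative relative to a per-SNP mixed model, as expected
  for the two-step scheme.
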