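# Methods

## The interaction model and its two variance estimators

Each marker is tested in the linear interaction model

    y = μ0 + βg·g + βe·E + βgxe·g·E + βc'C + βcxg'C·g + βcxe'C·E + ε

fit per SNP by ordinary least squares on complete cases (rows missing the
genotype, phenotype, environment or a covariate are dropped per SNP; no
genotype imputation in the regression).  A continuous environment is
centered before interaction columns are formed, which reduces collinearity
between `g` and `g·E`; the SNP main effect is then interpreted "at mean E".
A categorical environment (farm) is treatment-coded against the first
level in sorted order; the interaction is then a joint Wald test on the
levels−1 `g×farm` columns, and its p-value is invariant to the reference
choice (asserted in the tests to 1e-8).  Covariate×SNP and
covariate×environment columns are part of the model so that a confounded
covariate interaction cannot masquerade as a G×E signal.  Designs are
rejected (not silently repaired) when rank-deficient, with the collinear
columns named.

The coefficient covariance is computed two ways:

* model-based: `σ̂²(X'X)⁻¹` with a single residual variance — the estimator
  whose assumptions heteroskedastic data violate;
* sandwich: `(X'X)⁻¹ X' diag(c·w_i·e_i²) X (X'X)⁻¹`, which estimates a
  distinct variance per observation from the squared residuals.

Both p-values are always emitted; their genome-wide divergence is the
diagnostic for environment-dependent residual variance.

### Finite-sample flavor

`w_i` and `c` select the flavor: HC0 (`w=1, c=1`), HC1 (`c=n/(n−p)`), HC2
(`w=1/(1−h_i)` with leverage `h_i`), HC3 (`w=1/(1−h_i)²`), and the default
`BM` — Bell–McCaffrey: HC2 weights with a Satterthwaite reference df for
the one-column t test, computed as `(tr S)²/tr(S²)` for the quadratic form
`S = (I−H) diag(a_i²/(1−h_i)) (I−H)` under a homoskedastic normal
reference, evaluated in `O(np²)` through the rank-p structure of `H`.
The default matters at this package's target scale: with n ≈ 1000 samples
and p ≈ 73 design columns (3 covariates + 20 PCs and their interactions),
the package's own calibration experiment measures type-I error at α = 0.05
of roughly 0.060 for HC1, 0.053 for HC2, 0.039 for HC3 and 0.053 for BM,
against 0.07–0.08 for the model-based test under the heteroskedastic null.
BM is the recommended small-sample robust inference in the econometrics
literature and is what the acceptance experiments use; HC1 is retained for
compatibility with the plugin lineage of the method.  Multi-column (farm)
interactions use a Wald chi-square on the flavor's covariance (no
Satterthwaite df; a known small-sample gap documented here).

Reference distributions: t with `n−p` df (or the BM df) for one-column
tests; chi-square with levels−1 df for joint tests.  The genome-wide
engine (`interaction_scan`) shares each SNP's design across any number of
phenotype replicates and is asserted bit-consistent (1e-8) with the naive
per-SNP solver; SNPs that are monomorphic in the analyzed subset, or whose
interaction column has variance below 1e-12, are skipped with a reason
code, and a scan that skips more than half its markers aborts (it almost
always means misaligned inputs).

## Quality control

Filter order is deterministic and documented: samples with >10% missing
genotypes are dropped first; then markers are removed for (in order)
missing position, duplicate (chromosome, position), call rate <90%,
MAF <5% (computed on non-missing genotypes after the sample filter, all
samples treated as founders), Hardy–Weinberg exact p < 1e-6, and — when
trios are supplied — Mendelian error rate >2%.  Attribution is to the
first filter that removes a marker, which makes reports reproducible and
the procedure idempotent.  The HWE test is the exact conditional test
(heterozygote-count enumeration via the stable midpoint recurrence), with
a 1-df chi-square variant available; monomorphic markers return p = 1 by
convention.  Mendelian errors count trios whose child allele count is
impossible given the parents', over trios with all three genotypes
observed.

## Mixed-model baseline

The main-effect GWAS baseline fits `y = Xβ + u + e`, `u ~ N(0, K σa²)`,
`e ~ N(0, I σe²)`, with `K = WW'/m` from centered, variance-standardized
genotypes (mean-imputed; mean diagonal exactly 1).  REML is profiled on
the ratio λ = σa²/σe² over log10 λ ∈ [−5, 5] after one eigendecomposition
of K (coarse grid + Brent refinement); per-SNP tests hold λ̂ fixed and run
GLS in the whitened space (the EMMAX approximation — adequate for checking
that interaction hits lack main effects, not for exact per-SNP variance
re-estimation).  With K = I the likelihood is flat in λ (V ∝ I); the lower
bound is returned by convention, total variance is preserved, and the
per-SNP tests reduce exactly to OLS (asserted to 1e-6).  The GRM is built
from the same panel that is tested; proximal contamination is a known,
accepted caveat at this scale.

## LD tools and diagnostics

r² is the squared Pearson correlation of unphased allele counts over
shared non-missing samples (PLINK's composite default).  Clumping is
greedy by ascending p (ties by chromosome, position, id) with a 1 Mb
default window, verified against a brute-force restatement of the rule on
random instances.  LD scores sum bias-adjusted r² (`r² − (1−r²)/(n−2)`)
within 1 Mb, in-sample (the emulated study has no external reference
panel), self term 1.  The LD score regression of χ² on ℓ uses single-step
weights `1/max(ℓ,1)` — deliberately simpler than the iterative weighting
of the reference software, sufficient for an intercept-direction
diagnostic — and a leave-one-block-out jackknife SE over 50 contiguous
blocks (fewer than the reference software's 200 because desk-scale panels
have fewer markers).  λ_GC is median χ² over 0.4549.

## Gene and gene-set aggregation

SNPs map to a gene when within 50 kb of its bounds (1-based, inclusive;
multi-gene assignment allowed).  The gene statistic is the mean of
χ²₁-transformed interaction p-values.  Its null accounts for LD through
the genotype correlation matrix R: for correlated standard normals,
cov(z_i², z_j²) = 2r_ij², so Var(T) = (2/m²)·Σ_ij r_ij², and T is
moment-matched to χ²_ν/ν with ν = 2/Var(T) (Satterthwaite).  Two
degeneracies anchor the approximation and are asserted exactly:
independence recovers the χ²_m closed form, and perfect LD collapses to
ν = 1, reproducing the single-SNP p.  A seeded multivariate-normal
sampling fallback (100k draws) covers degenerate moments and doubles as a
cross-check: the two routes agree within |Δlog10 p| < 0.2 for 95% of
simulated genes.  Competitive gene-set analysis regresses gene
Z = Φ⁻¹(1−p) on set membership plus gene-size covariates (SNP count and
its log; constant covariates are dropped rather than destabilizing the
fit), one-sided for enrichment; sets need ≥2 analyzed member genes, and
the Bonferroni denominator is the analyzed-set count of the run at hand.

## Synthetic cohorts: what they emulate and what they do not

The generator mirrors the structure of a multi-farm cattle cohort:

* Genotypes: haplotype pairs with per-marker target MAF ~ U(0.05, 0.5) and
  first-order latent copying (probability `ld_decay`, default 0.6) that
  yields tunable adjacent-marker r² with exact marginal frequencies;
  ~3 kb marker spacing.  No mutation/recombination model, no realistic
  cattle demography.
* Environment: 7 farms with annual-mean temperature baselines
  (6, 5, 7, 4, 15, 17, 16) °C following a ~46°N → ~25°N latitude gradient;
  a ±15 °C seasonal sinusoid and 2 °C monthly noise; each individual's
  exposure is the mean over birth → recording, with recording at the trait
  age (default 12 months) ± 1 month.  An exact 12-month window averages
  the sinusoid to zero, so exposure variance is dominated by farm
  baselines and birth-season effects — a bounded, platykurtic
  distribution, as real mean-temperature exposures are.
* Phenotype: the generative model is the fitted model, with the continuous
  interaction score centered (a pure interaction SNP then has no marginal
  main effect, the signature the scan targets) and residual
  ε ~ N(0, σ0²·exp(δ·z(E))) with z the standardized environment — the
  canonical heteroskedastic violation (δ = 0 gives homoskedasticity).
  Defaults: σ0 = 40 kg, μ0 = 200 kg, farm offsets of ±tens of kg, matching
  growth-weight scales.
* Trios: Mendelian transmission without recombination, with a configurable
  child genotyping-error rate, solely to exercise the Mendel filter.

Passing tests on these cohorts show the estimators and their calibration
behave as designed under the assumed generative structure; they cannot
certify behavior under real-chip LD, pedigree structure, selection, or
non-normal residuals.

## Experiment sizes and numerical choices

The calibration experiments (`gweiskit.experiments`, also driven by
`scripts/acceptance.py`) use desk-scale sizes chosen so a full run takes
minutes on one core: type-I calibration with one genome replicate
(n = 1000, m = 2000, ld_decay = 0, δ = 0.8) and 200 phenotype replicates;
LD score intercepts on an ld_decay = 0.6, m = 5000 panel with 10 phenotype
replicates; effect recovery at n = 2000, m = 500 with 20 causal SNPs and
βgxe ∈ {0.5, 1, 2} kg/(allele·°C) over 25 replicates; heritability
recovery at n = 1000, m = 2000, h² = 0.5; gene/set null uniformity with
1000 three-SNP genes and 50 random 20-gene sets.  The covariate set for
calibration is sex, age, birth weight and 20 genotype PCs; the recovery
experiment omits PCs because PCs of a desk-scale panel place ~n_pcs/m of
any causal interaction inside the PC×E nuisance columns, visibly
attenuating β̂ (at chip scale the leakage, ~20/600k, is negligible).  The
type-I assessment quotes the binomial 95% CI for one scan's worth of tests
(N = m); the replicates stabilize the rate estimate but are not
independent tests, since tests sharing a phenotype replicate are
correlated.

Other numerical conventions: Cholesky solves of the per-SNP normal
equations; PCA by SVD of the standardized, mean-imputed panel with the
sign fixed by the largest-magnitude loading; rank checks by pivoted QR on
norm-scaled columns with tolerance `max(n,p)·1e-9`; p-values floored at
the smallest positive double; eigenvalue clipping at 1e-8 before
correlation-matrix Cholesky; ties in clumping broken by (chromosome,
position, marker id) for determinism.

## Known limitations

* EMMAX fixed-ratio approximation (no per-SNP REML); no
  leave-one-chromosome-out GRM.
* Multi-df robust Wald tests lack a Bell–McCaffrey-style df correction.
* LD score weighting is single-step; no attenuation or sample-overlap
  correction (single-cohort setting).
* The gene-level null uses genotype correlations as a stand-in for
  interaction-z-score correlations; accurate in the tested regimes, but an
  approximation whenever covariates correlate strongly with genotypes.
* Binary traits, variance-QTL tests, two-step screening designs, dosage
  formats and spline environments are out of scope.
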