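# Methods

## Outcome, QC and containers

The outcome is the natural log of per-course duration in days, held as
an `n_subjects x n_courses` array with NaN marking missing cells.
Course-level QC masks durations below 20 or above 100 days (bounds
inclusive; such values indicate relapse, censoring or recording error)
before the log transform; the filter is idempotent, with a 1e-9
relative guard so that exp/log round trips do not re-drop boundary
values. Genotypes are minor-allele dosages in {0,1,2} (int8, -1 for
missing) with BIM-style metadata; PLINK .bed/.bim/.fam I/O implements
the standard 2-bit SNP-major codec directly and is round-trip
bit-stable. The reader preserves the file's A1 coding by default (A1
is conventionally the minor allele); `orient="minor"` re-orients any
SNP whose coded-allele frequency exceeds 0.5.

Per-SNP QC removes SNPs with call rate < 0.95, MAF < 0.01, or exact
Hardy-Weinberg p < 1e-5 (all thresholds configurable). The HWE test is
the exact conditional test, enumerating the heterozygote-count
distribution given the allele counts in log-factorial space and summing
the probabilities of outcomes no more probable than the observed one
(with a 1e-12 relative tie guard).

## Kinship, relatedness, PCs

The kinship estimate is the standard GRM on sample allele frequencies,
`K_il = m⁻¹ Σ_j (x_ij − 2p_j)(x_lj − 2p_j) / (2p_j(1−p_j))`, with
per-SNP mean imputation of missing dosages and monomorphic SNPs
excluded. Relatedness pruning is greedy: while any off-diagonal
exceeds the threshold (default 0.125, third-degree), drop the subject
with the most super-threshold partners, breaking ties by larger
absolute row sum and then lexicographically smaller id. Ancestry PCs
come from the SVD of the standardized genotype matrix scaled by
`sqrt(m)`, so the reported eigenvalues are the GRM's; score signs are
fixed by making each column's largest-magnitude entry positive.

## Association engines

All three engines stack the observed cells, drop subjects with a
missing genotype for the SNP under test (casewise deletion), build
fixed effects [intercept, SNP dosage, course indicators (reference
course 1), optional PCs], and report a Wald χ²₁ test of the SNP
coefficient.

**PC-LMEM.** Subject random intercept. REML profiles the residual
variance and optimizes the single ratio `γ = σv²/σ²` by bounded scalar
search on the log scale (boundary `γ = 0` checked explicitly),
exploiting the closed-form inverse and determinant of compound-symmetric
blocks, so a fit costs O(N) after per-subject aggregation. Fixed
effects and their covariance come from GLS at the estimated (or
supplied) components. Cross-checked in the tests against
statsmodels MixedLM and against dense multivariate-normal likelihood
evaluations.

**PC-GEE.** Gaussian identity-link GEE: iterate GLS under an
exchangeable working correlation whose parameter is moment-estimated
from normalized residual cross-products each step; standard errors are
the robust sandwich. If the moment estimate leaves the positive-definite
range it is clipped toward independence and the fit flagged. Matches
statsmodels GEE to near machine precision in the tests. Model-based
(naive) SEs are not offered; the robust variance is the field standard.

**KIN-LMEM.** Stacked covariance
`σu²(K ⊗ J_J) + σv²(I_n ⊗ D) + σ²I`, restricted to observed cells; D
is exchangeable with fixed off-diagonal `d_rho` (default 0.5; identity
and full-matrix D are accepted). The course fixed effect is included
by default so the mean structure matches the competing models — the
bare form (no course effect) is available via `include_course=False`.
With complete data and exchangeable D the covariance diagonalizes in
the product of K's eigenbasis and a constant-first course basis, giving
O(nJ) likelihood evaluations after one n×n eigendecomposition; REML
then runs Nelder-Mead over the three log-variances. Incomplete data
fall back to a dense Cholesky likelihood (guarded to ≤ 6000 cells —
beyond desk scale the complete-data path or component reuse should be
used). The spectral objective is verified against the dense one, and
`loglike()` is always evaluated densely so it can serve as an
independent check of the fast path.

**Scan driver.** `run_gwas` defaults to component reuse: the variance
components are estimated once from the covariate-only null model and
reused for every SNP's GLS test (the standard mixed-model-GWAS
approximation); `mode="exact"` refits per SNP. On 200-SNP null panels
the two modes agree with p-value correlation above 0.99 (tested). The
GEE is refit per SNP in either mode, since it has no reusable
components. Non-converged and monomorphic SNPs keep their result rows
with NaN statistics and a cleared `converged` flag, and are excluded
from downstream comparisons.

Variance components are kept nonnegative by optimizing log-variances;
estimates below 1e-10 (relative to the outcome variance) are reported
as boundary zeros. With near-identity kinship, complete balanced data
and exchangeable D, `(σu², σv²)` are separated only by the off-diagonal
kinship signal, so the REML surface has a soft ridge; the SNP test is
insensitive to position along that ridge because the implied marginal
covariance is essentially constant on it.

## Evaluation framework

`qq_data` pairs sorted observed −log10 p with uniform expected
quantiles and computes λ as the median observed χ²₁ statistic over the
exact χ²₁ median (0.4549364). Genomic control divides χ² statistics by
λ only when λ > 1 (no anti-deflation) — a monotone, rank-preserving
correction. Concordance is Pearson r and r² on raw p-values, with the
−log10-scale companion also reported since the convention varies.
Cross-method ROC treats one method's sub-threshold calls
(p < 0.5/0.1/0.01/0.001/0.0001) as labels and another's −log10 p as
scores; AUC uses the Mann-Whitney midrank identity, equal to
trapezoidal integration of the returned ROC points (property-tested),
and degenerate label sets yield NaN rather than an error. Rare-SNP
stratification reports the MAF < 0.05 fraction in five p-value bins
that partition (0, 1]. `error_rate_harness` runs a seeded
(MAF, β) × method × α grid, counting rejections (p ≤ α) with Wilson
intervals: β = 0 cells share one phenotype across many null
SNP-replicates; power cells simulate one causal SNP per replicate.

## Synthetic cohort generator

Genotypes follow the Balding-Nichols model: ancestral MAF per SNP
(uniform on a range, or listed), per-subpopulation frequencies
`Beta(p(1−F)/F, (1−p)(1−F)/F)` at differentiation `fst`, genotypes
Binomial(2, p_sub); SNPs are independent (no LD). Phenotypes follow
the KIN-LMEM generative law with configurable `(α, β, γ, σu², σv², σ²,
D)`; correlated subject effects use a Cholesky square root of `σu²K`
with a 1e-8 jitter fallback and eigenvalue clipping only for exactly
semidefinite inputs. All draws flow from `numpy` Generators seeded as
`[seed, stream]`, so identical configurations are bit-identical.

Default calibration emulates the motivating cohort: 624 subjects, 4
courses, overall median duration 36 days with IQR ≈ 32–42 days. On the
log scale the IQR ratio gives `τ = log(42/32) / (2·z₀.₇₅) ≈ 0.20`, so
`α = log 36` and total variance 0.040, split as σu² = 0.020,
σv² = 0.008 (d_rho = 0.5), σ² = 0.012 — within-subject correlation 0.6,
reflecting the strong intra-individual correlation of course lengths.
A symmetric log-normal cannot match the slightly asymmetric 32–42
target exactly; the implied quartiles are 31.5 and 41.2 days
(verified against the closed-form quantiles in the tests).

Missingness: MCAR drops observed cells independently at a given rate;
MAR is monotone logistic dropout — from course 2 onward a
still-observed subject drops out with probability
`expit(intercept + slope·(Y_prev − center))`, `center` defaulting to
the mean first-course outcome, and stays out afterwards, so dropout
depends only on observed history. Defaults (intercept −1.4, slope 2.0)
give roughly 20% dropout per course at the cohort calibration with a
clear selection effect on later-course means.

## Study designs used by the checks, and their limits

- **Between-method concordance (acceptance script):** 600 subjects, 4
  complete courses, 5,000 null common SNPs (MAF 0.05–0.5), phenotype
  from the PC-LMEM generative law with σv² = 0.4, σ² = 0.6. On this
  design the three engines' p-values agree to r ≥ 0.99 and
  cross-method AUC ≥ 0.99 at p < 0.01. Desk-scale sizes were chosen so
  the whole comparison reruns in about a minute.
- **Null calibration:** 10⁴ common null SNPs; PC-LMEM rejection at
  α = 0.05 is required inside the 99% binomial band and λ within
  [0.95, 1.05].
- **Rare-variant behavior:** on 10⁴ null SNPs with MAF 0.01–0.05 the
  GEE rejects more than the mixed model at α = 0.001, and on a mixed
  panel its smallest p-values are enriched for rare SNPs — the known
  small-sample anticonservatism of the sandwich variance when
  minor-allele carriers are few.
- **MAR contrast:** with a true effect of 0.2 log-days/allele,
  strongly correlated courses (σv² = 0.8, σ² = 0.2) and steep dropout
  (intercept −1.0, slope 3.0), 500 replicates at n = 600 show the
  GEE's mean effect-estimate bias exceeding the mixed model's in
  magnitude. This contrast is a genuinely MAR-sensitive regime; with
  weak within-subject correlation or shallow dropout the two methods'
  biases are statistically indistinguishable at this replicate count —
  GEE's MAR invalidity is a real but regime-dependent effect.
- **Component recovery:** separating σu² from σv² needs off-diagonal
  kinship signal, so the recovery check simulates 150 families of 4
  (K = 0.5 within family) and averages REML estimates over 8 seeded
  replicates; truth (0.3, 0.4, 0.3) is recovered within 20%. With a
  near-identity GRM from an unrelated cohort a single realization can
  sit far along the ridge described above while fitting the marginal
  covariance equally well.

What the generator does **not** emulate: linkage disequilibrium,
genotyping error, imputation uncertainty, time-varying covariates,
relapse-driven (possibly MNAR) missingness, or admixture beyond
discrete Balding-Nichols subpopulations. Passing these checks
demonstrates correctness of the estimators and the direction of the
method contrasts under the stated generative laws — not performance on
real cohort data with those additional features.

## Open design choices, resolved

- The log transform is the natural log.
- D's structure is not dictated by the motivating analysis; it defaults
  to exchangeable with `d_rho = 0.5` in the fitter (a middling course
  correlation), and the generator default matches.
- The number of PCs defaults to 3 (the model as written) with any k
  available via `n_pcs` (the motivating analysis used 7 in places).
- GEE standard errors are robust; whether the original used robust or
  model-based SEs is unrecorded, and robust is the standard choice.
- Subject-level covariates (age, sex, treatment arm) can be carried in
  the phenotype table but are not entered into the shipped model
  designs, which adjust for course and PCs only.
- Rejection is counted as p ≤ α in the harness so α = 1 is exactly
  rate 1.
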