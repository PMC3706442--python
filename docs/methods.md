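# Methods

This note documents the statistical models implemented in `triherit`,
the numerical choices behind them, what the synthetic cohort generator
does and does not emulate, and the package's known limitations.

## Twin variance components

**Model.** Phenotypes are pooled-standardized (mean 0, variance 1) so
estimates read directly as variance fractions. Each zygosity group
contributes a bivariate-normal likelihood with common mean `μ`, common
variance `v = a² + x² + e²` (`x²` is `c²` for ACE-family models, `d²`
for ADE), and within-pair covariance `a² + x²` (MZ) or `a²/2 + c²` /
`a²/2 + d²/4` (DZ). Pairs with one missing member contribute their
univariate marginal density — full-information likelihood — so
singletons still inform `μ` and `v`. Degrees of freedom are reported as
(number of observed phenotype values) − (number of free parameters);
both raw counts are carried on the fit object so any alternative df
accounting can be reconstructed.

**Optimization.** Raw variances are optimized under nonnegativity
bounds by L-BFGS-B (tight tolerances: `ftol 1e-14`) started from the
constrained Falconer decomposition, with a bound-clipped Nelder–Mead
polish as fallback. This removes any dependence on an SEM framework.
Standard errors come from a central finite-difference Hessian of the
deviance with evaluation nodes shifted inside the bounds, delta-methoded
to the normalized fractions. Estimates within 1e-6 of the zero bound
are flagged `at_boundary`; their Hessian SEs are reported untruncated
(so a boundary estimate can legitimately print as `0.00 (0.02)`).

**AIC convention.** `aic()` returns the deviance-based form
`−2LL − 2·df` (with `df` the residual degrees of freedom), because that
is the convention of the model-comparison tables this package mirrors;
the textbook parameter-count form `−2LL + 2k` is exposed as
`VarCompFit.aic_parameters`. Likelihood-ratio differences within
numerical noise (|Δ| < 1e-6) are clamped to 0, so an ACE-vs-AE contrast
with C on the boundary prints `Δχ² = 0, p = 1`.

**Intraclass correlation.** The one-way ICC is computed in
method-of-moments form (equal denominators for the between- and
within-pair sums of squares), which is algebraically identical to the
Pearson correlation of the double-entered pairs; the df-corrected ANOVA
form differs at O(1/n) and would break that exact equivalence. The SE
is the Fisher-z delta approximation `(1 − r²)/√(n_pairs − 3)`.

**Falconer constraint logic.** Raw estimates are `a² = 2(rMZ − rDZ)`,
`c² = 2·rDZ − rMZ`, `e² = 1 − rMZ`. When the DZ correlation is less
than half the MZ correlation the raw heritability exceeds rMZ (a
non-additive signature); with `constrain=True`, `c²` is clamped to
[0, rMZ] and `a² = rMZ − c²`, preserving `e²` and the partition
`a² + c² = rMZ` while capping heritability at the MZ correlation.

**Summary-structure fits.** `twins_from_summary` whitens standard-normal
draws by the empirical Cholesky factor and recolors by the target, so
each zygosity group's *sample* moments equal the requested correlations
exactly; an ML fit to this data is the summary-likelihood fit implied by
printed correlations and pair counts. It is deterministic under a seed
(the construction consumes randomness only for the orthogonal part,
which the moments do not constrain).

## GRM and GREML

**GRM.** The GCTA estimator with sample allele frequencies:
off-diagonals average `(x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1 − p_i))`
over SNPs non-missing in both individuals (per-pair counts are kept);
diagonals use the adjusted estimator
`1 + Σ(x² − (1+2p)x + 2p²)/(2p(1−p))/m_j`, unbiased for 1 under HWE.
Because frequencies come from the analyzed sample, standardized columns
sum to zero, which forces the mean off-diagonal to about `−1/(n−1)`
rather than 0 — an intrinsic property of the estimator worth knowing
when sanity-checking a GRM.

**Unrelated-set pruning.** While any pair exceeds the cutoff (default
0.025), the individual in the most offending pairs is removed (ties:
lower call rate, then id order). On random small instances this greedy
rule is within one removal of the brute-force minimum (tested).

**REML.** The model has a single variance ratio, so instead of
iterative AI-REML updates the restricted likelihood is profiled
analytically over the total variance and maximized over
`h² ∈ [0, 1]` on the eigenbasis of the GRM projected onto the
covariate-orthogonal subspace (QR complement, one `eigh`): a coarse
grid (step 0.01) brackets the optimum and bounded Brent refines it to
`xatol 1e-12`. This is globally robust — the profile is evaluated
everywhere, so no starting-value or step-halving heuristics are needed —
and the optimizer is verified against a 0.001-step grid oracle and
against the textbook `log|V| + log|X'V⁻¹X| + y'Py` deviance in tests.
The SE is the observed information of the profiled deviance (central
second difference, nodes pulled inside the bounds); boundary fits are
flagged. A GRM numerically proportional to the identity makes the two
components unidentifiable and raises an error rather than returning an
arbitrary split.

**Composite heritability.** Averaging the three ages shrinks residual
variance: for per-age heritability `h²` and cross-age residual
correlation `r`, the composite's heritability is
`h² / (h² + (1 − h²)(1 + 2r)/3)` (0.60 for `h² = 0.5, r = 0.5`). Tests
therefore check per-age recovery directly and check the composite
against this closed form.

## Longitudinal equal-effect score test

**Null model.** Per-age means are regressed on covariates (intercept,
sex, cohort, optionally ancestry PCs). Coefficients are initialized by
per-age OLS and refined by two generalized-least-squares sweeps under
the pooled 3×3 residual covariance `Σ̂` (pairwise-complete estimate,
re-estimated between sweeps; if `Σ̂` is not positive definite the
independence working covariance is used, with a warning). The GLS
refinement matters: it makes the score identity
`Σᵢ Wᵢ'Σ_{s(i)}⁻¹ rᵢ = 0` hold exactly at the null estimates, without
which the score acquires a covariate-projection bias exactly in the MAR
settings the test is designed for. Individuals enter through whichever
ages they were observed at; an individual with no measurements is
inadmissible (the composite's at-least-one rule) and is filtered by the
caller. Ages with too few observations to fit the covariate model are
dropped with a warning.

**Statistic.** For SNP dosage `g` (missing dosages mean-imputed), the
efficient score for a single effect common to all ages is
`U = Σᵢ gᵢ·1'Σ_{s(i)}⁻¹ rᵢ`, with variance
`V = Σᵢ gᵢ²·1'Σ_{s(i)}⁻¹1 − I_βγ I_γγ⁻¹ I_βγ'` (the second term removes
the cost of estimating the per-age nuisance coefficients); `U²/V ~ χ²₁`
under the null. Per-individual pieces depend only on the null fit, so a
genome scan reduces to three matrix products over the dosage matrix.
The test reduces exactly to the pooled univariate score statistic when
every individual is observed at a single age, and to the squared OLS
t-statistic for a single fully-observed age (both asserted in tests,
the latter to 1%). The allele whose dosage pushes the trait upward
(`U ≥ 0`) is labelled the risk allele.

**Genomic control.** λ = median(statistic)/0.45494 per stratum
(genotyped / imputed-one / imputed-both); statistics are divided by
max(λ, 1) — deflation is never applied — and re-referred to χ²₁.
Strata with fewer than 100 statistics are flagged unstable. Null
calibration at the design scale (20,000 SNPs, n = 2,000, cross-age
correlation 0.5, 20/30/60% MAR dropout) yields λ within sampling noise
of 1 (SE of the 20k-SNP median ≈ 0.017) and 5% type-I error inside its
99% binomial interval.

## Quality control

Filters run in fixed order — info, MAF, missingness, HWE, plate — and
each excluded SNP records the *first* rule it failed, so per-rule counts
partition the exclusions. Boundary semantics are strict (fail iff
info < 0.975, MAF < 0.01, missingness > 0.02, HWE p < 1e-20, plate
p < 1e-6); imputed SNPs are judged by tiered info thresholds
(≥ 0.98 imputed-in-both, ≥ 0.90 second-array) instead of the genotyped
cutoff. The info score is carried as SNP metadata assigned by the
simulator: it is a property of the genotype-calling/imputation step,
which this package does not model. HWE uses the Pearson χ²₁ test by
default — at a 1e-20 threshold the asymptotic and exact tests agree in
order of magnitude — with the conditional exact test behind a flag
(verified against enumeration). The plate-effect test is a one-way
ANOVA F-test of dosage on plate label, the simplest association between
a quantitative dosage and a categorical batch. Sample call-rate (0.97)
and heterozygosity (|z| > 3) thresholds are package defaults,
configurable and logged; relatedness removal uses GRM off-diagonals as
the relatedness proxy and iteratively drops the lower-call-rate member
of the worst pair.

**PCA / Tracy–Widom.** Dosages are frequency-standardized
(`(x − 2p̂)/√(2p̂(1−p̂))`, missing mean-imputed) and the top-k left
singular vectors returned. The number of significant components is
decided by the sequential Patterson procedure against tabulated TW1
critical values (0.9793 / 2.0234 / 3.2724 at α = 0.05 / 0.01 / 0.001).
The moment-based effective marker count is capped at the actual marker
count (minus components already claimed): uncapped, the moment estimator
overshoots by ~5% at desk-scale aspect ratios, which inflates the TW
statistic by about one SD and the false-positive rate several-fold;
with the cap the null exceedance rate is at the nominal 5% on Gaussian
spectra, while the estimator still takes over when LD lowers the
effective count.

**LD pruning** is the greedy left-to-right scan: a SNP is dropped when
its squared dosage correlation with any kept SNP among the previous
`window` (default 50) kept SNPs on the same chromosome exceeds `r²_max`
(default 0.2).

## Power

Analytic power is the exact noncentral χ²₁ tail beyond the central
quantile at α, equal to `Φ(√NCP − √c) + Φ(−√NCP − √c)`. Two NCP
conventions are exposed — `ratio` (`n·q²/(1−q²)`, the default) and
`simple` (`n·q²`) — because published power values computed with
external calculators rarely state which was used; at `q² ≈ 0.01` they
differ by well under a percentage point. The Monte-Carlo cross-check
simulates `y = βg + ε` with `β²·Var(g) = q²` and applies the
closed-form correlation t-test (algebraically the no-covariate OLS of
`snp_regression`), vectorized across replicates.

## Synthetic cohort generator

The generator reproduces exactly the structure the analyses assume:

* **Twins** — Gaussian liability with factor-sharing coefficients 1/0.5
  (A), 1/1 (C), 1/0.25 (D), 0 (E), matching the expected-covariance
  algebra of the twin model, so `E[rMZ] = a²+c²+d²` and
  `E[rDZ] = a²/2+c²+d²/4` hold by construction.
* **Genotypes** — independent biallelic SNPs in HWE, ancestral MAF
  uniform on a configurable range (default 0.05–0.5), optional
  Balding–Nichols subpopulation divergence (Beta-distributed
  subpopulation frequencies with parameter Fst), uniform missingness,
  round-robin plate assignment.
* **Phenotypes** — a genetic score over standardized causal dosages
  with `Var(g) = h²_SNP` in expectation, identical at every age;
  age-specific residuals multivariate normal with exchangeable
  correlation (default 0.5, an assumption — the cross-age correlation
  of the trait is not pinned down externally, so it is an explicit
  parameter); phenotype variance standardized to 1 *before* covariate
  effects are added, so `h²_SNP` stays interpretable as a proportion;
  per-age dropout is a logistic function of sex and cohort only
  (missing at random given covariates), with the intercept set to the
  target marginal rate — covariate spread pushes realized rates a
  percentage point or two off the target, which the tests tolerate.

What it deliberately does **not** emulate: linkage disequilibrium and
recombination maps (SNPs are exchangeable, so LD pruning is exercised
only against chance correlation), genotype-calling artifacts and real
info-score distributions, imputation-probability triples (dosages plus
an assigned info score only), assortative mating and shared-environment
/ genotype correlation, and non-Gaussian trait scales beyond what the
rank-normalization stage removes. Passing tests therefore demonstrate
the estimators' statistical correctness under their stated assumptions,
not robustness to the full messiness of array data.

## Problem sizes and reproducibility

All generators use `numpy.random.default_rng` and are bit-reproducible
under a fixed seed. Test and acceptance experiment sizes were chosen as
the smallest that leave the checked property comfortably outside
sampling noise: GREML recovery at n = 2,000 / m = 5,000; the score-test
null calibration at 20,000 SNPs / n = 2,000; twin fits at 1,099 + 1,787
pairs; replicate-based checks (Tracy–Widom nulls, SE-vs-n monotonicity)
at a few hundred samples per replicate. Single-draw checks of 2·SE
criteria fail ~5% of the time by construction, so null-recovery
assertions average a few seeded replicates rather than betting one draw.

## Known limitations

* Univariate twin model only: no cross-age (multivariate) decomposition,
  sex-limitation or rater-bias models.
* One genetic variance component in GREML: no GxE, multiple GRMs,
  bivariate GREML or BLUP prediction.
* The association scan is plain (not mixed-model) regression; GRM-aware
  association is out of scope.
* Sample-QC heterozygosity is computed from hard-called dosages and is
  meaningful only for genotyped (integer-dosage) panels.
* The exact-HWE path enumerates heterozygote counts and is intended for
  per-SNP use, not genome-wide scans.
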