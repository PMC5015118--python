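# Methods

## Model

For a set of m SNPs, let z = (z₁…z_m) be the single-SNP GWAS
z-statistics (zᵢ = βᵢ/seᵢ, or the signless |z| implied by the reported
p-value when β/se are unavailable — only squares enter the statistic).
Under the null hypothesis that no SNP in the set is associated,
z ~ MVN(0, R), where R is the Pearson correlation matrix of the allele
counts (the LD matrix), estimated from a reference panel. The set
statistic is T = Σ zᵢ² = zᵀz, distributed under the null as the
weighted mixture Σ λᵢ χ²₁ with λᵢ the eigenvalues of R. The set
p-value is P(T > T_obs), evaluated analytically.

Assumptions worth stating explicitly:

* The z-statistics and the reference panel describe the same
  population, so that reference LD approximates GWAS-sample LD. The
  test is empirically robust to moderate LD sampling error, but a
  mismatched ancestry panel degrades it.
* Summary statistics come from (approximately) independent samples per
  SNP-level test on a homogeneous cohort; relatedness or uncorrected
  stratification inflates all zᵢ and therefore T.
* The statistic treats effects as fixed and does not re-estimate them
  jointly; it tests the aggregate departure of the set from the null,
  not any particular multi-SNP model.

## Tail evaluation

`spectral_weights` eigendecomposes R symmetrically; eigenvalues below
1e−8·λ_max are clamped to zero and dropped (R is PSD in exact
arithmetic; small negative values are rounding noise, and duplicated
SNPs legitimately produce zero eigenvalues). The retained weights sum
to m within tolerance.

Three evaluators for P(Σλᵢχ²₁ > q):

* **Satterthwaite** moment matching: scale a = Σλ²/Σλ, degrees
  d = (Σλ)²/Σλ², p = SF(q/a; χ²_d). Exact when all λ are equal;
  percent-level error otherwise, worse deep in the tail.
* **Saddlepoint** (Kuonen): solve K′(ζ̂) = q for the CGF
  K(ζ) = −½Σlog(1−2ζλᵢ) by bracketed Brent iteration on
  ζ ∈ (−10⁸, (1−10⁻⁸)/(2λ_max)), then the Barndorff-Nielsen tail
  1 − Φ(w* + log(v/w*)/w*) with w* = sign(ζ̂)√(2(ζ̂q − K(ζ̂))),
  v = ζ̂√K″(ζ̂). Excellent relative accuracy deep in the tail (the
  regime that motivates an analytic test); a few percent relative
  error in the body, worst for a single component. Within
  |q − Σλ| < 10⁻⁶·Σλ of the mean the formula is singular and we
  delegate to Satterthwaite (p ≈ 0.5 there, where moment matching is
  accurate).
* **Ruben's series**: the exact expansion
  P(T > q) = Σₖ aₖ·SF(q/β; χ²_{m+2k}) around the reference scale
  β = 2λ_min λ_max/(λ_min+λ_max), coefficients by the standard
  recursion aₖ = (2k)⁻¹ Σ_{r<k} g_{k−r} aᵣ, gₖ = Σⱼ(1−β/λⱼ)ᵏ. The
  series converges geometrically at rate (λ_max−λ_min)/(λ_max+λ_min);
  truncation is run to ~10⁻¹⁵ absolute (cap 20,000 terms). We refuse
  the series when the spectral ratio exceeds 0.999 (condition number
  ≳ 2000), where convergence is impractically slow.

**Default policy** (`method="auto"`): equal weights → the
moment-matched form, which is then the exact scaled chi-square;
otherwise the Ruben series; if its result is below 10⁻¹², where the
series' absolute truncation error is no longer negligible relative to
p, or if it refuses to converge, the saddlepoint; Satterthwaite as the
last resort. Rationale: the body of the distribution (p ≥ ~10⁻¹²)
should be exact — the approximations' percent-level body error is
measurable against a modest Monte-Carlo oracle — while the deep tail
needs *relative* accuracy, which is the saddlepoint's strength and the
absolute-error series' weakness. Each evaluator can be forced via the
method flag. The p-value is never a hard zero and has no resampling
floor.

## LD estimation and pruning

LD is the Pearson correlation of allele counts (genotypic r; reference
panels are unphased), computed after per-SNP mean imputation of missing
genotypes, symmetrized as (r + rᵀ)/2 with the diagonal forced to 1.
Monomorphic SNPs are an error naming the SNP. Allele orientation only
flips the sign of r and the test uses r² and λ, so no strand
harmonization is performed beyond requiring the unordered allele pair
to match between summary and panel.

Pruning at threshold t: build the graph of SNP pairs with r² > t,
repeatedly delete the currently highest-degree vertex until no edge
remains. Finding the true smallest removal set is minimum vertex cover
(NP-hard); the greedy count-based heuristic is what we implement, and
tests verify it achieves the optimum on small instances where
greedy-by-degree is optimal. Degree ties remove the SNP latest in
positional order — deterministic, and deliberately independent of the
association statistics (pruning on p-values would bias the test). The
recommended default threshold is r² = 0.9; thresholds below ~0.7 are
not recommended. The top-SNP column is recorded before pruning so the
report cannot lose the strongest single-SNP signal.

## Pipeline

A gene's set is every summary-statistic SNP on the gene's chromosome
with reference-panel position in [start − W, end + W], W = 50 kb by
default; SNPs may belong to several overlapping sets. Per set:
intersect summary and panel (allele-checked), optionally prune, sum
the per-SNP χ², convert via the spectral weights of the kept SNPs' LD
matrix. Per-set failures (empty intersection, monomorphic SNP) skip
the set with a logged reason rather than aborting a genome-wide run.
The z² is taken from (β/se)² when both are present (more precision in
deep tails than inverting a printed p-value), from the χ²₁ quantile of
p otherwise; a flag flips the preference. The multiple-testing line in
the log is Bonferroni: α divided by the number of sets tested
(≈ 2×10⁻⁶ at 25,000 genes).

Reference-panel QC defaults: MAF ≥ 0.01, HWE p ≥ 10⁻⁶, missingness
≤ 0.02. The HWE test is a 1-df χ² goodness-of-fit of observed versus
expected genotype counts — the common choice of threshold matters far
more than the test flavor, and the threshold is a parameter.

## Synthetic cohorts

The simulator provides the conditions under which the method's
properties are demonstrated:

* **Unlinked SNPs**: frequency p ~ U(0.01, 0.99) per SNP, genotypes
  i.i.d. Binomial(2, p); 10,000 individuals by default.
* **Block LD**: a thresholded latent-Gaussian copula — two latent
  haplotype draws per individual, AR(1) within blocks, thresholded at
  each SNP's frequency quantile. Realized genotypic LD rises
  monotonically with the latent parameter but is attenuated by
  thresholding (latent 0.99 → genotypic r² ≈ 0.8 at moderate
  frequencies, worse at extreme frequencies or mismatched thresholds).
* **Phenotypes**: y = Σⱼ wⱼβⱼ + e with wⱼ the standardized causal
  genotype; effect directions are drawn from N(0,1) and magnitudes set
  to √h² so each causal variant explains exactly the target fraction
  of variance (0.4% per variant in the unlinked power scenarios, 0.2%
  in the LD-pruning scenarios); residual variance is chosen
  analytically as 1 − k·h², not rescaled post hoc.
* **Clustered causals**: repeatedly pick a random 200 kb window, draw
  the cluster size from Binomial(50, 0.1), and fill from the window's
  common SNPs until 50 causal variants are placed.
* **Perfect-LD augmentation**: an exact copy of a chosen SNP's
  genotype column, for the duplication experiments.
* **Low-LD-causal sets**: one unlinked causal SNP plus blocks of null
  SNPs at latent AR(1) 0.999 sharing one moderate block frequency
  (realized r² ≈ 0.94; high-LD SNPs necessarily share frequencies, and
  mismatched thresholds would destroy the intended redundancy). This
  is the regime where pruning demonstrably gains power.
* **Marginal scan**: per-SNP simple linear regression (two-sided t
  test), producing `.ma`-style summary records; the permutation oracle
  uses the identical t² statistic so the two routes are comparable.

One integer seed drives everything through named independent streams
(genotypes / effects / residuals / placement / permutation), so any
sub-experiment reproduces in isolation.

What the synthetic data does *not* emulate: realistic haplotype
structure and recombination-driven LD decay (the copula's blocks are
rectangular), allele-frequency spectra from demography, imputation
error, relatedness, or case-control ascertainment. Passing tests show
the statistical machinery is correct under its stated model, not that
a specific real-data analysis will replicate; in particular the tests
of LD-pruning benefit construct the favorable regime (redundant
high-LD null markers, low-LD causals) deliberately.

## Validation set-up and problem sizes

The test suite and `scripts/acceptance.py` use desk-scale problem
sizes chosen to keep sampling error well below the effect being
demonstrated: closed-form limits up to m = 50; 50–100 random LD
matrices against a 10⁶-draw MVN oracle; 40–50 cohorts of n = 5,000
against a 10⁴-permutation oracle; 500–1,000 null sets for calibration;
120–200 replicates of n = 10,000, m = 20 sets for the power orderings;
25–40 replicates of six 19-SNP sets for the pruning comparison. The
permutation oracle is evaluated in vectorized chunks bounded to ~64 MB
of scratch.

## Known limitations

* The empirical-p convention (r+1)/(s+1) in the oracles is a choice;
  resampling tools differ in edge handling, which matters exactly at
  the floor the analytic method is free of.
* The saddlepoint's body inaccuracy means forcing
  `method=saddlepoint` can disagree with a large Monte-Carlo estimate
  by a few percent relative for mid-range p; the default policy avoids
  this.
* Cross-chromosome custom sets compute LD from the panel as-is
  (≈ 0 between chromosomes), which is correct but makes the weights
  nearly block-diagonal; no special handling.
* The greedy pruner is a heuristic; pathological LD graphs can make it
  remove more SNPs than necessary (never fewer than the post-condition
  requires).
* No support for dosage/BGEN/VCF input, shrinkage LD estimators, or
  conditional multi-signal dissection.
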