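# Methods

`rarestrat` is a simulation laboratory for studying how fine-scale
population structure distorts gene-based rare-variant association tests.
This note records the models, the defaults and why they were chosen, the
numerical conventions, and the limits of what the synthetic data can show.

## Demographic model and its calibration

Genetic data are simulated with msprime under a deliberately minimal
demography: a single ancestral population of constant effective size
N_anc = 10,000 diploids splits, `split_time_generations = 80` generations
before present, into two demes A and B joined by symmetric migration at
rate m per haplotype per generation (grid: 0, 0.001, 0.01, 0.025, 0.05,
0.1). An optional step expansion of the ancestral population is available
(`DemographyConfig.expansion`) but off by default: the scenarios under
study only vary post-split parameters, and the shared ancestral history
cancels out of the between-deme differentiation, which is dominated by 80
generations of drift against migration.

Two sizes describe each deme and they are deliberately distinct:

- `deme_haplotypes = 10,000` — the census panel sampled per gene, from
  which individuals are built and reference allele frequencies computed;
- `deme_effective_diploids = 10,000` — the coalescent size governing drift.

The effective size is a calibration, not a typo. A two-state coalescent
calculation (pair of lineages within vs between demes, coalescence rate
1/2N_e per generation, switch rate 2m) gives, for an 80-generation split
at m = 0.01, an expected F_ST ≈ c·(∫ within − ∫ between) ≈ 24·c with c
the per-generation coalescence probability. With 5,000 diploids per deme
this predicts F_ST ≈ 2.4e-3; with 10,000 diploids, ≈ 1.2e-3. Pilot
simulations confirm both. Only the larger size reproduces the
differentiation regime this package targets (multi-locus Weir–Cockerham
F_ST(m = 0.01) ≈ 1.2e-3, the neighboring-European-countries scale), so
10,000 diploids per deme is the default. Users modelling a different
census/effective relationship can set the two fields independently.

Per-gene sequence parameters: `region_length_bp = 10,000`,
`mutation_rate = 1.5e-8`, `recombination_rate = 1e-8` per bp per
generation. The region length was fixed by pilot runs so that a
2,000-individual sample analyzes on the order of 31 rare variants per
gene (pilot means: 30.9 at m = 0.01 to 32.4 at m = 0.1), the regime the
rest of the defaults assume. Mutations use a binary (0/1) model so every
site is biallelic; sites are 1-based bp coordinates and distances are
absolute coordinate differences.

## Variant classification and sampling design

Rare variants are defined by the minor allele frequency in the **full
deme-A panel** (10,000 haplotypes), not in the drawn sample, because
cases always originate from deme A; the default `rare_threshold` is 0.01
(configurable — only the "MAF ≤ 1%" tabulation convention anchors it).
Sites monomorphic in deme A are neither rare nor common; sites with
panel-A MAF ≥ 5% form the common set used for structure estimation.
Genotypes are recoded to counts of the allele that is minor in deme A.
Rare variants that happen to be monomorphic in a drawn sample are
retained in the matrix but excluded from the analysis view, so matrix
dimensions never change silently across permutations.

A case/control sample is 1,000 + 1,000 individuals (configurable).
Under H0, individuals are disjoint random haplotype pairs labeled
independently of genotype; the deme-B control quota (0/25/50/75/100% of
controls) is met exactly. Under H1, candidate deme-A individuals are
formed by random mating on the panel (haplotype pairs drawn with
replacement across candidates) and assigned case status with probability
logit⁻¹(α0 + β′X_rare); sampling repeats until the quotas are filled.
The effect model sets β_j = ln(1.5) for exactly round(0.5 · #rare)
uniformly chosen deleterious variants and 0 elsewhere. The baseline α0
defaults to logit(0.1); with fixed quotas it changes sampling efficiency,
not the estimands. Deme-B controls are always drawn blind to genotype.

## Association statistics

All nine statistics act on the analyzed rare-variant matrix X (N × P
minor-allele counts), the phenotype Y, and null fitted means μ̂.

- **CAST**: collapsing score S_i = 1{Σ_j X_ij ≥ 1}.
- **Sum / wSum**: weighted score S_i = Σ_j w_j X_ij. Both feed the
  logistic score test U = S′(Y − μ̂), V = (Y − μ̂)′(Y − μ̂) ·
  (S − S̄)′(S − S̄)/(N − 1), Q = U²/V, with the covariate-projected
  variance replacing V when the null model has covariates.
- **aSum**: per-variant marginal score tests at level 0.10 (the source
  method's convention) flip the sign of variants significantly enriched
  in controls; the signed sum is then score-tested. Signs are recomputed
  inside every permutation.
- **KBAC**: individuals grouped by multi-site genotype; class l weighted
  by the hypergeometric upper tail P(H ≥ n_l¹), H ~ Hyp(N, N_l, N1); the
  statistic is the squared weighted sum of case/control frequency
  differences over *all* classes including wild type, as the defining
  formula sums l = 0…L (a switch excludes the wild-type class for
  cross-checking against the original software's carrier-only sum — for
  a single carrier class the two agree).
- **SKAT / SKAT-O**: Q_ρ = (Y − μ̂)′XW R_ρ WX′(Y − μ̂) with
  R_ρ = (1 − ρ)I + ρ11′; SKAT is ρ = 0, SKAT-O optimizes over
  ρ ∈ {0, 0.1, …, 1}.
- **PODKAT**: the same quadratic form with the triangular position
  kernel A_jj' = max(1 − d_jj'/w, 0), default radius w = 1,000 bp.
  Weights default to 1 (the weighting-scheme comparison is defined for
  Sum and SKAT; any weight vector can be passed).
- **DoEstRare**: ∫ |p̂¹f̂¹(pos) − p̂⁰f̂⁰(pos)| dpos over [1, L_g], where
  f̂ are Gaussian KDEs of case/control rare-allele positions and p̂ are
  binomial-tail-weighted mean allele frequencies, w_j = P(M_j¹ ≤ m_j¹)
  under B(2N1, MAF̂_j⁰). Numerical choices (the source specifies
  neither): trapezoid rule on a 1,024-point uniform grid, bandwidth by
  Silverman's rule on the **pooled** allele-position sample so the
  bandwidth — like the kernel columns — is permutation-invariant and can
  be precomputed. The weighted frequencies are normalized by Σw_j; any
  common normalization rescales the statistic without affecting its
  permutation p-value.

Weighting systems for Sum/SKAT: uniform; Beta(1, 25) density at the
total-sample MAF; 1/√(N·MAF(1 − MAF)) with the total-sample MAF; and,
for Sum only, the same form with the control-only pseudo-count estimator
MAF̂⁰_j = (Σ_controls X_ij + 1)/(2N0 + 2). Monomorphic columns get
weight 0 under the total-MAF inverse-variance scheme (logged); the
pseudo-count keeps the control scheme finite.

## Significance

**Analytic route.** Burden scores use the 1-df chi-square of Q = U²/V.
Kernel statistics use the tail of Σ λ_k χ²₁ with λ the eigenvalues of the
covariate-projected half kernel; the tail is computed by numerical
inversion of the characteristic function (Imhof's integral, absolute
tolerance 1e-6, scale-normalized so proportional problems are bitwise
identical) with a four-moment fallback when inversion fails. SKAT-O
follows the optimal-test construction: per-ρ tails, then a
one-dimensional recalibration integral over the burden direction
η₀ ~ χ²₁, with the conditional κ tail evaluated by the four-moment
approximation for speed (the inversion is reserved for the per-ρ
p-values); the result is clamped to [min_ρ p_ρ, grid-size × min_ρ p_ρ].

Two small-sample refinements keep the analytic and permutation routes
mutually consistent, which the test-suite verifies directly:

1. Without covariates the kernel null variance uses the N/(N − 1)-scaled
   binomial variance — the exact second moment of the label-permutation
   null and the same convention as the printed burden V. This also makes
   the P = 1 kernel test identical to the score test.
2. The asymptotic mixture's mean/variance are matched to the exact
   permutation moments of the quadratic form (derived combinatorially,
   verified by exhaustive enumeration), and for very small samples
   (N ≤ 25 and at most 3·10⁵ label assignments) the permutation null is
   enumerated completely — the standard exact-resampling practice for
   small binary-trait kernel tests. Both refinements vanish at study
   scale (N = 2,000).

**Permutation route.** Adaptive permutation with p̂ = (b + 1)/(m + 1),
significance threshold α = 0.01 and precision c = 0.2 (defaults).  The
stopping rule — the cited procedure is not spelled out in its source —
is declared as: stop when the coefficient of variation of p̂ falls below
c, or when the one-sided 99% lower confidence bound of p̂ exceeds α;
budget 10/α permutations, minimum 20. Methods whose ingredients depend
on the case/control split (aSum signs, control-MAF weights, KBAC
weights, DoEstRare weights) recompute them inside every permutation and
default to this route; fixed-weight burden tests and the SKAT family
default to the analytic route.

## Stratification corrections

Ancestry covariates are the leading K principal components (default 2;
5 and 10 supported) of LD-pruned common variants. Pruning: MAF ≥ 5% in
the full deme-A panel, greedy sliding window of 50 variants, step 5,
pairwise r² < 0.2, keeping the higher-MAF member of a conflicting pair
(only the thresholds are anchored; window mechanics are this package's
choice). PCA columns are centered at twice the allele frequency and
scaled by the binomial standard deviation, the ancestry-PCA convention;
a deterministic truncated SVD handles large panels.

- **PCA model correction (M1)**: the PCs enter the logistic null model;
  score and kernel statistics use covariate-adjusted residuals and
  projected variances. Applicable to the regression-representable tests
  with label-free weights (CAST, Sum, total-MAF wSum, SKAT, SKAT-O,
  PODKAT). Complete or quasi-complete separation — e.g. when 100% of
  controls come from deme B and ancestry fully explains the phenotype —
  raises an explicit error, which is why that scenario is excluded from
  correction.
- **PCA permutation correction (M0)**: the null model contains only the
  PCs; per-individual disease odds θ_i = exp(α0 + α′Z_i) then drive a
  stratification-preserving permutation in which exactly N1 case labels
  are resampled from the multivariate Fisher's noncentral hypergeometric
  law. (The published weight definition exponentiates a probability;
  it is read as the odds, the quantity it is named as — the literal
  variant is available behind `literal_exp_probability`.) Sampling is
  exact: independent Bernoulli draws with odds ∝ θ, globally tuned so
  the expected total is N1, conditioned on the total by rejection. θ is
  fitted once per gene, not refitted per permutation. Applicable to
  every test, including KBAC and DoEstRare.

In experiments, each replicate's PCs are computed from the sampled
individuals' genotypes at a fixed pool of background genes (individuals
persist across genes as haplotype-index pairs). Pool sizing matters:
at migration 0.001 a 100-gene pool (~450 pruned common variants) leaves
the correction weak, while a 400-gene pool (~1,900 variants) restores
SKAT's type-I error to nominal — consistent with the eigenvector
phase-transition requirement F_ST ≫ 1/√(N·L). The experiment harness
defaults used in the acceptance battery use 400 background genes.

## Experiments and summaries

A replicate is one simulated gene with one case/control sampling; seeds
derive from a master seed via `numpy` seed sequences, so entire scenario
tables are bit-reproducible. Rejection rates at α = 0.05 are reported
with two intervals: the binomial null-consistency band centered at α
(the calibration yardstick) and a rate-centered Wilson CI. Replicate
failures (no analyzable variants, separation) are logged, excluded and
counted, never silently dropped.

Desk-scale replicate counts were fixed from confidence-interval widths
before any result was inspected: 2,000 replicates for nominal type-I
error (band [0.0404, 0.0596]), 1,000 for inflation direction, 200 for
the paired correction and power comparisons; the full-scale 10,000/1,000
design remains reachable through configuration.

## What the generator does and does not emulate

It emulates: post-split drift/migration differentiation at realistic
magnitudes (F_ST anchored at the printed value), site-frequency spectra
with roughly half of variants rare at the 1% threshold, per-gene
analyzed-variant counts near 31, exact control-origin quotas, and a
logistic disease model confounded with ancestry when controls are
mismatched. It does not emulate: the worldwide multi-population history
(bottlenecks, growth — the ancestral expansion is off by default),
sequencing error or missingness, linkage between genes, covariates other
than ancestry, or deme-specific growth rates (which published work flags
as able to reverse the burden-vs-kernel sensitivity ordering). Passing
tests therefore demonstrate correctness of the statistical machinery and
directionally faithful behavior of stratification effects, not
quantitative transfer of any specific rate to real cohorts.

## Known limitations

- SKAT-O's recalibration integral uses the four-moment tail internally;
  its accuracy is verified against permutation only to Monte-Carlo
  precision on small instances.
- The adaptive-permutation stopping rule is an interpretation of a cited
  but unspecified procedure; different readings change permutation
  counts, not validity (the (b + 1)/(m + 1) estimate is conservative
  under any stopping time).
- `wc_fst` supports exactly two populations (the study design); the
  estimator is the 1984 ratio-of-sums form without missing-data
  handling, which the simulation never produces.
- The VCF writer emits an arbitrary phase for heterozygotes; haplotype
  phase carries no information in this pipeline.
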