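# Methods

## Model and procedure

The pipeline tests haplotype alleles — distinct haploid allele strings
within sliding centimorgan windows — for association with a binary trait
in a cohort that may contain close relatives.

**Windows.** For each window size s ∈ {1, 0.5, 0.25} cM, anchors start at
the genetic-map position of the chromosome's first SNP and advance by s/4
while the anchor lies before the last SNP's position. A window collects
the SNPs whose interpolated map position falls in the half-open interval
[anchor, anchor + s); windows with fewer than five SNPs, including
truncated chromosome tails, are dropped. Anchoring at the first SNP
(rather than at map coordinate zero) makes the tiling a deterministic
function of the panel alone; windows with identical SNP content at
different anchors are kept, since the overlap structure matters for fine
mapping. Map positions come from piecewise-linear interpolation of the
Map(cM) column of a HapMap-format recombination map in bp, clamped at the
map boundaries.

**Haplotype statistics.** Each distinct allele string A in a window is
collapsed against the pooled alternative a, giving diploid classes AA, Aa
and aa. The allele frequency is p = (2·AA + Aa) / (2n), and departure
from Hardy–Weinberg proportions is measured by the Pearson statistic
Σ(obs − exp)²/exp over the three classes with expectations
(p²n, 2pqn, q²n). Collapsing to two alleles leaves one estimated
parameter, so the statistic has 1 df and the QC cut at χ² > 24
corresponds to a tail probability just under 10⁻⁶. Alleles with
p outside [0.005, 0.995] or χ² > 24 are flagged `merged`: excluded from
testing but retained inside every kept allele's alternative, so kept
alleles' dosages are unaffected by QC. Genotype counts pool all
individuals, related or not; a founders-only frequency is available
separately for comparison with frequencies computed on unrelated subsets.

**Relatedness.** G is the standard centred-and-scaled SNP GRM,
G_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i)), over
QC-passed autosomal SNPs with MAF ≥ 0.01; allele frequencies default to
analyzed-sample estimates. G_t zeroes off-diagonal entries strictly below
0.05 (diagonals kept), retaining only close relationships. Fitting G and
G_t together lets the model absorb distant population structure and
family covariance on separate variance components. Note that
thresholding does not preserve positive semi-definiteness; see the
numerical notes.

**Mixed model.** The trait is analysed on the observed 0/1 scale:
y = Xβ + Z₁u + Z₂v + ε with u ~ N(0, G σ²ᵤ), v ~ N(0, G_t σ²ᵥ),
ε ~ N(0, I σ²ε), and X holding intercept, sex, age, age² (plus batch and
centre for a replication-style single-GRM fit). Variance components are
estimated once under the null (no haplotype term) by
average-information REML with an EM-REML fallback and an active-set
treatment of components pinned at the non-negativity floor; convergence
is declared when the restricted log-likelihood changes by less than
1e-8 (at most 200 iterations). Each haplotype's 0/1/2 dosage d is then
tested by a GLS Wald statistic with the null V held fixed, the standard
MLMA scan convention: β̂ = d′Py / d′Pd, se = (d′Pd)^(-1/2), where P is
the REML projection matrix. Re-fitting variance components per haplotype
is possible but not the default; for a genome-wide scan the fixed-V
approximation is standard and orders of magnitude faster.

**Effect reporting.** Observed-scale effects are converted to odds ratios
by log(OR) ≈ β / (cf(1−cf)) with cf the sample case fraction — exact in
the limit of small effects for a linear model on a binary outcome — with
the 95% CI mapped the same way; an exact logistic refit (ignoring
relatedness) is provided as a cross-check, and agreement is within a few
percent for OR ≤ 2. A haplotype's population-level contribution to
variance is 2p(1−p)β², reported raw and, optionally, as a fraction of a
caller-supplied denominator. Both the phenotypic variance and the total
genetic variance (σ²ᵤ + σ²ᵥ) are legitimate denominators; the pipeline
emits both rather than choosing.

**Fine mapping.** Testing A against all other alleles in its window
dilutes the signal when overlapping windows carry similar haplotypes
tagging the same causal variant. Pairs of same-size-class haplotypes
whose windows share at least five consecutive SNPs, both with P below
10⁻³ and effects in the same direction, are intersected; *every* maximal
run of at least five consecutive agreeing SNPs becomes a new haplotype
(one pair can yield several), re-tested on all individuals with the same
null-model projection. A refined allele imposes fewer constraints than
its parents, so its frequency is at least the larger parent frequency,
and a refined allele identical to a parent reproduces the parent's
P-value exactly.

**Multiple testing and meta-analysis.** Approximately independent tests
are counted by greedy LD clumping: results sorted by ascending P (ties by
chromosome, then start position); each unassigned haplotype becomes an
index and absorbs unassigned haplotypes on the same chromosome within
1,000 kb whose dosage r² with it is ≥ 0.4. The Bonferroni level is
0.05 / n_clumps. Genomic inflation λGC is the median implied 1-df χ²
divided by 0.454936 (the χ²₁ median, carried to six digits). Cohorts
combine by fixed-effect inverse-variance weighting on the log-OR scale:
weights 1/se², combined se (Σw)^(-1/2). Printed odds-ratio rows are
converted back to (log-OR, se) via se = (ln hi − ln lo)/(2·1.959964).

**Replication power.** Under a multiplicative per-copy risk model with
genotype relative risk GRR and population haplotype frequency f, the
case-chromosome frequency is p_case = f·GRR / (1 + f·(GRR − 1)); with
screened controls the population frequency decomposes as
f = K·p_case + (1 − K)·p_ctrl, yielding the control frequency given
prevalence K. Power is that of the two-proportion z-test on allele
counts (2·n_case vs 2·n_control chromosomes) with the pooled-variance
null SE and the alternative-variance SE, evaluated two-sided. At GRR = 1
the power equals α exactly; the analytic value agrees with a Monte-Carlo
simulation of the same test within ±0.02.

## Synthetic cohorts

The generator emulates the data regime the pipeline assumes, with every
random draw descending from one seed through a named SeedSequence
hierarchy (map, founders, planting, meiosis, phenotype), so equal seeds
give byte-identical cohorts.

* **Map** — one chromosome, constant rate (default 1 cM/Mb), physical
  positions jittered around even spacing; defaults 2,000 SNPs over 5 cM.
* **Founder haplotypes** — a first-order Markov copying model: each
  founder haploid copies from a pool of 30 ancestral haplotypes
  (themselves drawn with target MAF uniform on [0.01, 0.5] and local LD),
  switching pool members with probability 1 − exp(−d_cM / 0.5) per SNP
  interval — an expected copying-segment length of 0.5 cM — plus a
  per-SNP mutation rate of 0.002. This gives long shared haplotypes,
  realistic within-window allele counts (tens of common alleles per
  window rather than thousands of singletons) and direct control over
  haplotype frequencies; those properties, not coalescent realism, are
  what the pipeline's statistics depend on.
* **Families** — sizes drawn from a distribution patterned on a
  family-based population cohort (many singletons, mostly 2–4-member
  families, a thin tail up to 31). Two-member families are sibling pairs
  with ungenotyped parents; larger families are two genotyped parents
  plus children. Offspring haploids are crossover mosaics of the
  parental haploids with crossover counts Poisson(L_cM/100) and uniform
  positions on the map.
* **Phenotype** — liability = sex, age and age² covariate terms
  (defaults 0.10, 0.10, 0.05 on centred covariates; age uniform 18–99,
  sex Bernoulli(0.5)) + planted causal effects (β per dosage copy)
  + a pedigree-correlated polygenic term of variance h² (default 0.3)
  + Gaussian noise of variance 1 − h². Cases are the individuals above
  the empirical (1 − K) liability quantile, so the realized prevalence
  matches the target K (default 13.9%, discovery-like; 34.0% mimics a
  questionnaire-ascertained replication cohort) regardless of the
  covariate contribution to the liability variance.
* **Planted causal haplotypes** — over a span of ≥ 5 consecutive SNPs
  (default 8), the existing founder allele closest to the target
  frequency is selected; if no allele is within ±25% relative, founder
  haploids are minimally edited (copied onto or resampled from other
  strings) to hit the target. The truth ledger records allele strings,
  spans, target and realized frequencies, effect sizes, prevalence,
  threshold and the full pedigree.

**What the simulator does not emulate:** coalescent/ARG genealogies,
genotyping or phasing error, imputation uncertainty, multi-chromosome
genomes, X-linked inheritance, assortative mating, or ascertainment bias
beyond prevalence. Passing tests therefore demonstrate the statistical
machinery — calibration under the null, recovery of planted effects,
Mendelian and frequency bookkeeping — not performance on the LD
idiosyncrasies of real array data.

## Numerical choices

* REML starts residual-heavy (20% of phenotypic variance split across
  genetic kernels) because a thresholded GRM can be indefinite: with few
  markers, sampling noise in G leaves spurious off-diagonals ≥ 0.05 and
  G_t acquires negative eigenvalues. V factorizations escalate a ridge
  (up to 1e-3 of the mean diagonal) before declaring non-PD; AI steps use
  step-halving with an EM fallback, and components at the 1e-6·var(y)
  floor with inward gradients are held fixed (active set). A
  near-singular AI matrix at convergence (condition > 1e8) flags the fit
  `unidentifiable` — e.g. when a kernel is the identity and aliases the
  residual.
* Aliased fixed-effect columns are dropped deterministically, last-in
  first; a tested dosage inside the column span of X raises an error
  rather than returning a 0/0 Wald statistic.
* Dosage-based tests are skipped (with a reason) for alleles monomorphic
  in the analyzed set; P-values are floored at the smallest positive
  double.
* Half-open window intervals and strict QC inequalities (χ² > 24 merges;
  exactly 24 is kept; GRM off-diagonals exactly 0.05 are retained)
  resolve all boundary ties one way, deterministically.
* Clump membership requires the same chromosome and an edge-to-edge gap
  ≤ the distance window (default 1,000 kb) in addition to the r²
  condition; input order cannot affect the result because the visit
  order is the P-then-position sort.

## Test problem sizes

Simulation-backed checks run at sizes chosen to keep the default suite
fast while leaving the assertions statistically meaningful, and all are
seeded: REML parameter recovery uses 40 replicates at n = 400 (bias
bound ±0.05 on true components 0.5/0.5); null-scan calibration uses one
cohort of n = 2,000 with h² = 0 and ~4,500 tested alleles (λGC within
[0.95, 1.05], Kolmogorov–Smirnov uniformity P > 0.01); end-to-end
recovery uses 12 replicates at n = 1,200 with a causal haplotype
spanning a full 0.25-cM tiling window and a liability effect sized for
80% analytic power at the scan's Bonferroni-corrected threshold
(0.05 / ~2,000 tests), requiring the causal window among the top-10 hits
in ≥ 90% of replicates. The sibling-GRM check pools three cohorts
because per-pair GRM entries are noisy when LD limits the effective
marker count.

## Known limitations

* The observed-scale linear mixed model is the analysis model, not a
  GLMM; its Wald P-values are well calibrated at the allele frequencies
  the QC admits for cohort sizes in the thousands, but become
  conservative/lumpy at very small minor-allele counts (binary outcome,
  few carriers). The QC frequency floor exists precisely to keep tests
  in the calibrated regime.
* The OR conversion is an approximation; for strong effects (observed
  β approaching the case fraction) it overstates the OR. The logistic
  cross-check quantifies this per haplotype.
* Replication assumes identical ref/alt orientation and SNP order
  between cohorts; no strand flipping or allele matching is attempted.
* Diplotype (haplotype-pair) tests, dominance models, BGEN/PLINK binary
  input, X-chromosome handling and LD-score-regression diagnostics are
  out of scope.
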