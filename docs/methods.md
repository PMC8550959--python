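# Methods

## Model and pipeline

The analysis treats every data domain the same way: a nonnegative
subjects × features matrix `X` is approximated by `X ≈ WH` with
`W ∈ ℝ₊^{n×k}` (subject loadings) and `H ∈ ℝ₊^{k×p}` (feature
loadings), fitted by multiplicative updates on the Frobenius objective.
Missing cells carry a 0/1 mask: they contribute neither to the
objective nor to the updates, so no imputation enters the factorization
itself.  One factor yields one *set* — the subjects and features whose
loadings pass the membership policies below — and sets are pooled over
a whole rank range (default 2–8 for phenotype domains, 2–8 for
genotype, 2–10 for environment), so structure is represented at several
granularities, exactly as a multi-resolution clustering would.

Relations between two set collections over one cohort are tested on the
shared-subject count with three statistics: the exact upper-tail
hypergeometric probability (summed in log space via `logsumexp`, so a
tail of 1e−300 keeps full relative accuracy), the two-sided Fisher
exact probability (exact rational summation for tables up to total
count 1000, scipy beyond), and an empirical permutation p with the
add-one correction `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`.
Significance is the conjunction of the BH-corrected analytic test
(`q ≤ α`, default α = 0.05; a raw-threshold mode is available) and the
permutation test (`p ≤ perm_alpha`).  With the default 1999
permutations the attainable floor is exactly 5·10⁻⁴, which is the
default working threshold; when a caller lowers `n_perm`, the unset
threshold adapts to the attainable floor instead of silently becoming
unsatisfiable.

The significant relations form a weighted source × target matrix
(−log₁₀ of the hypergeometric p, capped at 300 to avoid infinities;
overlap-count and binary weightings available).  NMF of that matrix at
rank k (default 3, fixed — no automatic selection at the network level)
assigns each set to its maximal factor.  Sets with no significant
relation receive no network: an argmax over a zero row is arbitrary and
would drag the set's subjects into a random network.  Subjects join the
network holding the weighted plurality (> 50%) of their max-normalized
set memberships, *and* must carry total membership weight above a
quarter of the median member support.  That support floor is the
package's realization of a "significant association" threshold for
subjects: sets accumulate as near-copies across the rank range, so a
genuine member of one domain's block carries roughly half the median
two-domain support, while a background subject brushed by one or two
stray sets carries far less.  Networks are finally renumbered 1..k by
ascending mean well-being of their assigned subjects, making the
network index an ordinal health axis.

Well-being is the top decile of the product of the three character
scale totals (SD × CO × ST, each total the sum of its subscale
columns); ill-being is the bottom decile of SD + CO.  Decile flags use
a strict-quantile rule: with `k = ceil(0.1 n)` the cutpoint is the
(k+1)-th extreme order statistic and only strictly more extreme scores
are flagged — distinct scores flag exactly k subjects, ties at the
boundary flag fewer (never more), and an all-ties cohort flags nobody.
The two flags are not mutually exclusive; their overlap fraction is
reported.  ANOVA uses the textbook sums of squares (cross-checked
against scipy in the tests); zero within-group variance reports F = ∞
with a flag.  Tukey HSD comes from scipy.

Genotype and environment matrices are biclustered identically (dosage
and ordinal exposure codes are already nonnegative).  A derived set
associates with a network when its members are enriched in the
network's subject pool (hypergeometric + BH across the set × network
grid, plus a permutation test that shuffles subject labels — within
ancestry strata when the optional genotype-PC stratification is on).
Environment sets are *directly* networked when they significantly
overlap a temperament or character set of the network, *indirectly*
networked when they overlap a network-associated SNP set (a
set-theoretic gene–environment chain; no causal mediation estimand is
computed), and *both* when both hold.

Variance explained: the outcome is the subject's network index (1..k,
ordered by well-being, treated as numeric), each subject's genotype
(environment) predictor is the mean set-level health probability of the
genotype (environment) sets containing the subject (grand-mean imputed
and counted when a subject is in none), and three OLS models
(genotype-only, environment-only, joint) are scored by the mean
out-of-fold R² of stratified 10-fold cross-validation.

Replication matches sets across cohorts by shared features, since the
subjects differ: similarity is the hypergeometric enrichment of shared
feature ids over the joint namespace, identical signatures match
unconditionally (the enrichment p of a near-universal feature set is
bounded away from zero even against its own copy), and a greedy
best-first one-to-one matcher below a threshold (default 0.05; an
optimal-assignment variant is provided) pairs the collections.  A
discovery relation replicates when both endpoint sets match and the
matched pair is significant in the replication graph.  The matched
fraction is calibrated by permuting the replication collection's
feature labels.

## Numerical and design choices

* **Initialization.**  The deterministic extraction path uses a seeded
  k-means indicator initialization (`n_init = 10`): the Frobenius-
  optimal dense solutions reached from NNDSVD reliably merge one
  planted block into the baseline factor, whereas a cluster-indicator
  start targets exactly the block structure the extraction is after
  (its final objective is slightly worse — block recovery and
  Frobenius fit are different goals).  NNDSVD (with canonical SVD
  signs, making the path equivariant under subject permutation) is
  used for relation-matrix partitioning and profile clustering, and
  random uniform starts drive the consensus runs of rank selection.
* **Membership policies.**  Subjects: a parameter-free bimodal (Otsu)
  split of the loading column, which adapts to the loading spread; the
  fixed relative-max rule (`loading ≥ frac × max`, frac = 0.5) is
  available and remains the default on the feature axis, where weights
  are few and crisp.  Under member-loading noise the relative-max rule
  clips a block's tail against its outlier maximum, which is why it is
  not the subject-axis default.
* **Set-quality guards.**  Factors covering more than 34% of the
  cohort are dropped (with three near-disjoint networks a genuine
  subgroup cannot exceed about a third of subjects; near-uniform
  factors describe the baseline).  Factors whose members are not
  distinctively *high* on the factor's own features (non-positive mean
  contrast against non-members) are dropped: additive NMF also emits
  noise-floor factors whose "members" are the low scorers, and those
  are not biclusters.
* **Rank selection.**  Consensus stability (fraction of random-start
  runs co-clustering two subjects by dominant factor) is scored by the
  cophenetic correlation between consensus dissimilarity and its
  average-linkage dendrogram; ranks within 0.02 of the best value are
  retained.  A degenerate (zero-variance) consensus is reported as
  perfectly stable (1.0) with a warning.  The pipeline default
  accumulates sets over the whole rank range; stability-restricted
  accumulation is a config switch.
* **Convergence.**  Multiplicative updates stop when the relative
  objective decrease falls below `tol` (default 1e−5) or after
  `max_iter` (default 200); the per-iteration objective trace is
  recorded and is non-increasing to 1e−9 relative.
* **Determinism.**  Every stochastic stage's seed is spawned from one
  `SeedSequence`; serialized results (sorted-key JSON, fixed TSV
  dialect, no timestamps) are byte-identical across reruns.

## The synthetic generator

`generate_cohort` emulates the statistical structure the analysis
assumes, with all defaults forming the reference conditions: 2000
subjects, 16 temperament + 13 character subscales (labeled NS1–PS4,
SD1–ST3, partitioning into the seven named scales), 1000 SNPs, 15
environment variables, three networks, 5% unassigned background,
additive effect size 2.0 over noise SD 1.0, disjointness 0.9, MAF
uniform on (0.05, 0.5].

Feature side (drawn from the *structure* seed): features partition into
per-network pools; each pool splits disjointly among the network's
planted sets (defaults: one temperament and one character set, two SNP
sets, two environment sets per network), and each set borrows
`(1 − disjointness)` of its size in features from other networks'
pools — the borrow sequence is fixed before the dial applies, so
cross-network feature sharing is exactly monotone in the dial and zero
at disjointness 1.  Subject side (drawn from the *subject* seed, so two
calls with different subject seeds give twin cohorts over one ground
truth): phenotype blocks each cover 85% of their network pool and
their union covers it fully, so every labeled subject carries
phenotype signal; a reserved 25% slice excluded from SNP blocks hosts
direct-only environment sets; SNP blocks span the rest of the pool
plus 80% of the network's background share, whose environment
co-occurrence realizes indirect (gene–environment) wiring; "both" sets
straddle.  Phenotype scores are a truncated-normal baseline (mean 1.0,
clipped at 0) plus the additive shift on planted cells; genotypes are
Hardy–Weinberg draws with planted blocks' allele frequency raised by
`0.2 × effect_size` (capped at 0.95); environment variables are
ordinal 0–3 (binomial with success 0.25 background, 0.85 in planted
cells — graded exposures such as parental warmth or income);
missingness is MCAR.  An optional three-population ancestry confound
(`structure_strength` > 0) shifts per-population allele frequencies to
exercise PC stratification.

What the generator does *not* emulate: linkage disequilibrium,
genotyping error, item-level questionnaire structure, non-random
missingness, measurement floor/ceiling effects, or cohorts whose
networks differ in size.  Passing recovery tests therefore shows the
pipeline recovers idealized planted structure at realistic noise — not
that real cohorts contain such structure.  Two structural consequences
are worth knowing: indirect-only environment blocks live inside the 5%
background by construction, so at default size (~25 subjects) they are
usually too small to recover as biclusters (the wiring-logic tests use
truth-derived sets and larger background fractions instead); and the
environment-only R² is small on default cohorts because recovered
environment sets cover only part of each network.

## Problem sizes in the test suite

Unit tests run on constructed micro-examples and cohorts of 200–800
subjects; the end-to-end recovery guarantees run at the full reference
conditions (n = 2000, 1000 SNPs, ten seeds), the null-calibration
checks at n = 2000 over twenty seeds, the replication monotonicity
sweep at n = 600 with three seeds per effect size, and determinism at
n = 400 with genotype and environment included.  The whole suite
completes in a few minutes on one CPU.

## Known limitations

* NMF is a local optimizer; the k-means start makes block recovery
  reliable on block-structured data but offers no global guarantee.
* Accumulating sets across ranks intentionally produces near-duplicate
  sets; downstream counts (e.g., "33 temperament sets") describe the
  pooled multi-granularity collection, not distinct subgroups.
* The subject support floor assumes set copies accumulate over several
  ranks; with a single-rank collection it reduces to a weak filter.
* Cross-cohort matching assumes a shared feature namespace; SNP panels
  are intersected by id and non-shared variants dropped.
* Ordinal network index in OLS treats adjacent networks as
  equidistant; this mirrors the design it benchmarks, not a modeling
  recommendation.
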