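# Methods

This note documents the models and estimators implemented in `pigpop`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions a user auditing results will
want to know.

## Data model and conventions

Genotypes are diploid biallelic dosages (0/1/2 alt alleles) with a
distinguished missing sentinel that is never conflated with a reference
call; every statistic skips missing entries in its own denominator.
Coordinates are 1-based inclusive throughout (VCF convention); BED input
is converted on read, and an interval's span is `end − start + 1` bp.
Phased data carry an explicit 2n × L haplotype matrix; the phase flag is
set only when every genotype separator in the input indicates phase.
Multiallelic records are rejected by default (chip data are biallelic;
silent splitting hides upstream errors) and split into biallelic records
on request. Variant filtering uses strict inequalities — "MAF below the
threshold" removes a SNP, so a SNP at exactly the threshold survives —
and the filter report counts SNPs failing each rule and both.

## Diversity statistics

Per SNP with n called alleles and alt frequency p, nucleotide diversity is
the unbiased pairwise heterozygosity π̂ₛ = n/(n−1)(1 − p² − q²). The breed
value is the mean of π̂ₛ over assayed SNPs (monomorphic SNPs contribute 0).
This is a per-assayed-SNP average appropriate to chip data; it is *not*
sequence π per bp, which would divide by covered genome length. PN is the
fraction of assayed SNPs at which both alleles are observed in the group
(entirely missing SNPs still count in the denominator); Ho is the
proportion of called genotypes that are heterozygous, averaged over SNPs.
π requires ≥ 2 called alleles; groups of one sample are rejected.

## Fst estimators

Two per-SNP estimators are exposed because they disagree in exactly the
regimes this pipeline meets:

* **Weir–Cockerham (1984)** two-population θ from the a, b, c variance
  components; the default, matching the tooling convention of chip-era
  pipelines. Per-SNP values may be negative (retained; clamped to 0 only
  when a matrix is used as a distance). Mean Fst is the ratio of sums
  Σa/Σ(a+b+c) ("weighted"); the per-SNP arithmetic mean is also reported.
* **Hudson/Bhatia** ratio estimator
  [(p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1)] / [p₁q₂ + p₂q₁] with allele
  counts n — hand-checkable, and the recommended choice when sample sizes
  are grossly unequal.

A SNP is undefined (NaN, excluded from means and quantiles) when either
group has fewer than two called alleles or the union is monomorphic.

The choice matters for three-population contrasts in which the two
contrast groups are *pools of breeds* roughly ten times the focal sample:
W–C's θ assumes each group is an unstructured random-mating unit, and a
breed pool's internal structure (Wahlund effect) inflates its within-group
heterozygosity components, deflating θ at precisely the strongly
differentiated loci a scan cares about (in the packaged sweep scenario the
planted locus reads ≈ 0.68 under W–C against ≈ 0.79 under Hudson). The
scan therefore defaults to W–C for continuity but the power scenario in
`scenarios.py` uses Hudson, and the estimator is recorded in every scan
result because it changes outlier identity.

## LSBL scan

For focal population A against contrast groups B and C, the per-SNP
locus-specific branch length is x = (Fst_AB + Fst_AC − Fst_BC)/2. The
identity x_A + x_B + x_C = (Fst_AB + Fst_AC + Fst_BC)/2 (summing the three
focal choices) holds algebraically and is asserted in tests to machine
precision. Negative x is legal and never clamped.

Outliers are flagged as x strictly above a threshold. Two threshold modes
are first-class because published analyses mix them: an empirical tail
quantile (default top 0.02% of *defined* x values, implemented as the
(k+1)-th largest with k = ⌊n·fraction⌋, so exactly k SNPs exceed it up to
ties) and an absolute cutoff (e.g. 0.8). Candidate genes are those
harboring an outlier SNP (inclusive) or with an edge strictly less than
the 10-kb flank from one; the strictness at exactly 10,000 bp follows the
definition's "less than".

A caution established quantitatively in the test suite: under pure
equal-drift nulls the absolute-0.8 cutoff is only clean at moderate
differentiation. With Balding–Nichols drift F = 0.05 (n = 15/group,
20k SNPs) no replicate in 100 produces x > 0.8; at F = 0.2 the *true*
(infinite-sample) branch length exceeds 0.8 roughly four times per 20k
SNPs per replicate, so every replicate contains "outliers" that are
extreme drift, not selection. Absolute cutoffs do not transfer across
differentiation levels; the empirical quantile does.

## ROH calling

The caller mirrors the PLINK `--homozyg` scheme with the published window
parameters (50-SNP windows, ≤1 heterozygote, ≤5 missing, ≥500 kb) and the
companion parameters that tool leaves implicit, exposed in `ROHParams`:
minimum 100 SNPs per segment, per-SNP window hit-rate threshold 0.05,
1000-kb maximum gap between consecutive SNPs, and at most 50 kb per SNP
(density). Candidate runs are split at large gaps and trimmed to the
outermost homozygous non-missing SNPs. Chromosomes shorter than one
window yield no calls. Length bins are half-open: [0.5, 1), [1, 5),
[5, ∞) Mb. The definition is frozen by a brute-force window-enumeration
oracle in the tests; on planted ≥1-Mb tracts the caller's boundary error
is bounded by about one window span, because windows straddling a tract
edge tolerate only one outside heterozygote.

## LD decay

r² is the squared Pearson correlation of dosage vectors over samples
called at both SNPs (composite genotype LD — no phase needed). SNPs are
pre-filtered within the analysis group (MAF > 0.1, call rate > 0.9,
nonzero variance) and pairs are taken within 1000 kb. The decay curve is
the Sved/Heifetz expectation E[r²|d] = 1/(1 + βd_kb), fitted by nonlinear
least squares **on all pairs**: fitting only pairs above a reporting
threshold (as the r² ≥ 0.3 reporting convention might suggest) would bias
β downward, so the 0.3 cutoff is applied only to the report, never the
fit. r²₀.₃ = (1/0.3 − 1)/β in closed form; a binned-mean crossing reader
is provided as an alternative reporting mode. A fit whose curve stays
above 0.99 across the observed window is declared degenerate (r²₀.₃ =
+∞ with a warning).

## Haplotype analyses

Region haplotypes come from the phased matrix; any copy with a missing
allele in the region is dropped and counted, not imputed — phased chip
data are nearly complete and auditability beats a few recovered copies.
The network is a deterministic Kruskal minimum spanning tree under
Hamming distance (edges ordered by weight, then lexicographic endpoint
pair), with rejected equal-weight closures kept as annotated alternative
edges; this replaces randomized network layouts with a reproducible
construction. The frequency filter "greater than 10" is strict (count ≥
11). Shared-fixed-block detection computes, per SNP and target
population, the allele frequency over called haplotypes and marks a SNP
eligible when one shared allele reaches the fixation threshold (default
0.95 — "nearly fixed" is not quantified in the source literature, so the
parameter is exposed and tested at 0.90/0.95/1.00) in *every* target;
maximal eligible runs are returned with 1-based inclusive spans. Carrier
status for association is dominant (≥1 copy of the reference haplotype);
the association runs a two-sided F-test on the variance ratio at α = 0.05
and then a pooled-variance t-test (or Welch if equal variances are
rejected), reporting both groups as mean ± sd. Tag SNPs are chosen by
greedy set cover over still-confounded haplotype pairs with position as
the tie-break.

## Synthetic data

The generator is the package's test bed and defines what "passing" means.
Population allele frequencies follow Balding–Nichols: ancestral p ~
Uniform(0.05, 0.95) per SNP, population frequency ~ Beta(p(1−F)/F,
(1−p)(1−F)/F), so F equals that population's expected Fst against the
ancestor and — as measured by the recovery tests — the W–C ratio-of-sums
mean between two populations drifted at F matches F within a few percent
at 20k SNPs, n = 50. SNP spacing averages 2,689 bp, the chip's mean
inter-SNP distance. Two genotype modes: independent Bernoulli draws per
haplotype (no LD; the null for LD sanity checks and scan calibration),
and a Li–Stephens-like mosaic of per-population founder panels with
per-bp copying-switch probability, which produces monotone distance-decaying
r² and discrete founder haplotypes into which blocks are planted. Sweeps
override a focal population's frequency at chosen SNPs (optionally
pinning the ancestral frequency so the contrast groups drift around a
known value); ROH tracts overwrite the second haplotype with the first;
traits are y = μ + β·carrier + N(0, σ) with a hemoglobin-like baseline
(μ = 138 g/L) by default.

What the simulator does *not* emulate: ascertainment bias of chip SNP
selection (except via the frequency range), linkage between chromosomes,
mutation, genotyping error, admixture gradients, and realistic demography
(growth, migration). Passing tests therefore demonstrate correctness of
the estimators and detectors under their stated models, not robustness to
every artifact of real chip data.

Frozen study designs (`scenarios.py`): the sweep-power scenario uses 20
breeds × 15 animals at F = 0.1 with the focal breed scanned against two
pooled groups of 9 and 10 breeds — mirroring the pooled-contrast design
of the study this emulates — with the selected locus driven 0.2 → 0.99;
the null scenario is three breeds × 15 at a chosen F; the shared-block
scenario uses 12 populations × 10 with a 26-SNP block planted at
frequency 1.0 in 5 targets, a 12-founder panel, and ancestral frequencies
Uniform(0.2, 0.8) (ascertained-common-variant range) so that chance
same-allele fixation across all five targets has probability ≤ ~10⁻⁶ per
SNP.

## Numerical conventions and determinism

All randomness flows through `numpy.random.default_rng` seeds carried in
configs; identical configs give byte-identical outputs, and the pipeline
manifest records a parameter hash and SHA-256 per artifact. Neighbor
joining breaks Q-criterion ties by the lexicographically smallest pair of
subtree labels, making topology independent of input order; negative NJ
branch estimates are clamped to zero with the deficit moved to the sister
branch and logged. LD pruning sweeps windows repeatedly until a full pass
removes nothing, so the surviving set provably contains no within-window
pair above the r² threshold; the dropped member of a violating pair is
the lower-MAF SNP, ties to the later position. PCA mean-imputes missing
dosages per SNP before frequency standardization and fixes each
component's sign so its largest-magnitude loading is positive. Problem
sizes in tests and the acceptance script (20k SNPs, 50-100 replicates,
≤5000-SNP oracle comparisons) were chosen as the smallest designs at
which the targeted effects are comfortably resolved.

## Known limitations

* Statistical phasing is out of scope; haplotype analyses require phased
  input (or the simulator's phased output).
* The W–C implementation is the two-population θ; multi-population θ
  across r > 2 groups is not provided (pairwise matrices cover the use
  cases here).
* The ROH caller reproduces a frozen, oracle-tested definition of the
  sliding-window scheme; other tools' trimming details may differ at
  segment edges by a few SNPs.
* IBS distances do not satisfy the triangle inequality in general; they
  are used for clustering, not metric embedding.
* The PED/MAP reader assigns ref/alt by lexicographic order of observed
  alleles (alt = 'N' for monomorphic SNPs), which loses the original
  strand/allele labels that binary PLINK files would carry.
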