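# Methods

This note documents the models, decision rules and numerical choices
behind `holosplit`, and what the synthetic benchmark does and does not
establish about real data.

## Partitioning model

A holobiont assembly is a mixture of contigs from the host genome, the
symbiont transcriptome, and other organisms. The classifier consumes
per-contig alignment evidence against two pooled databases (multiple
host references and multiple symbiont references are pooled before
comparison) and applies a three-branch rule:

* hits in exactly one database → exclusive call for that class;
* hits in both → the single best hit over the combined hit set decides.
  "Best" is ranked by bitscore, then lower e-value, then longer
  alignment, then host before symbiont. The final tie-break is
  arbitrary but documented, so output is deterministic and invariant to
  hit-row order;
* no hits → *other*.

Branch counts are kept in a ledger whose identities
(`exclusive + ambiguous + no_hit = total`,
`final class = exclusive + resolved-ambiguous`) are asserted at
construction, never assumed.

Hit evidence normally comes from an external aligner's 12-column
tabular output with an e-value cutoff of 1e-3 (rows at exactly the
cutoff are kept). The package also ships an alignment-free backend:
canonical k-mer containment (k = 21 by default) of each contig against
the pooled database k-mer sets, emitting a pseudo-hit when containment
≥ 0.2 with pseudo-bitscore = containment × contig length / k. With 2%
contig divergence the expected intact-k-mer fraction is
(1−0.02)²¹ ≈ 0.65, comfortably above the threshold, while random
k-mer collisions are negligible at k = 21; the screen is meant for
desk-scale validation and testing, not as an aligner replacement.

GC diagnostics use 1%-wide histogram bins; the mode is the centre of
the fullest bin (lowest bin on ties). The host/symbiont split should
reproduce the bimodal composition (~41.5% vs ~50.6% GC in the
motivating system).

## Redundancy reduction

Identity between two sequences is defined as the matched positions in
the optimal semi-global alignment — the shorter sequence aligned end to
end against the best region of the longer — divided by the length of
the shorter sequence (the convention of the classic greedy clustering
tools). Scoring is match +1, mismatch −1, gap −1 with free terminal
gaps in the longer sequence; among equal-score alignments the one with
the most matches is taken (implemented as a single integer DP over
score×K + matches with K greater than any match count, so score always
dominates lexicographically).

Greedy clustering processes sequences in descending length (ties by
id); each sequence joins the first cluster whose representative it
matches at or above the threshold, else founds a new cluster, making
the representative always the longest member. A k-mer prescreen
(k = 8 nt / 3 aa) skips only provably sub-threshold pairs: if matches
≥ t·L, at most ⌊(1−t)·L⌋ positions of the shorter sequence lie in
non-match columns and each destroys at most k k-mer occurrences, so the
multiset k-mer intersection is at least (L−k+1) − k⌊(1−t)·L⌋.
Multiset (not set) intersections are essential — repeated k-mers in
low-complexity sequences must count with multiplicity or the bound
fails. Admissibility is verified in tests by comparing clusterings with
and without the screen.

The cascade clusters nucleotides at 97%, translates the surviving
representatives via their longest ORF (ATG-to-stop over six frames,
standard code, ≥ 30 aa; stop-to-stop available behind a flag), and
clusters the peptides at 95%. Representatives lacking a qualifying ORF
bypass the protein level and are retained: coding potential is not a
membership criterion, and silently dropping ORF-less contigs would
shrink the reference set. Every input contig maps to its surviving
representative across both levels.

## Read cleaning

FASTQ reads (phred+33) are removed when their N fraction strictly
exceeds 5% (a read at exactly 5% is kept). Quality filtering at Q20 is
applied, by default, as 3′ trimming with a sliding mean window of 4
bases — the read is shortened while the trailing window averages below
Q20 — with a per-read mean-quality mode available; reads shorter than
25 bp after trimming are removed. The windowed rule can leave a couple
of low-quality bases adjacent to high-quality ones (the window mean
rescues them); this matches how window trimmers behave and is pinned by
a test.

## Expression stage

Counts are normalized with the trimmed mean of M-values: against a
reference sample (the one whose upper-quartile/library-size ratio is
closest to the mean of those ratios), gene-wise log2 ratios M and
abundances A are computed over genes positive in both libraries,
double-trimmed (30% of M per side, 5% of A per side by rank), and the
factor is 2 to the precision-weighted mean of the surviving M, using
delta-method weights; factors are rescaled to geometric mean 1. The
implementation is cross-checked against the reference R implementation
in a test. Two consequences worth knowing: a sample in which a subset
of genes is strongly inflated receives a factor *below* 1 (the
inflated genes consume depth, so the trimmed majority of M is
negative), and factors are only approximately invariant to rescaling a
library's depth, because the precision weights depend on absolute
counts.

CPM is 10⁶ × count / (library size × factor). All modelling
downstream uses log2(CPM+1): untransformed CPM has strongly
mean-dependent variance that a fixed-effects ANOVA cannot absorb.

Outlier samples are flagged from the average-linkage tree on
1 − Pearson correlation of log2(CPM+1): a sample is an outlier when
the height at which it first merges exceeds the median first-merge
height plus 3 × MAD (MAD scaled by 1.4826). This replaces a by-eye
dendrogram call with a reproducible rule; the per-sample false-positive
rate under homogeneous simulations is below 5%. Removal is guarded:
flagged samples are dropped most-isolated first, but never below two
replicates per phase, since the across-phase test is undefined there.

Differential expression is a per-gene one-way fixed-effects ANOVA on
log2(CPM+1) across the four phases, run separately per sex, with
Benjamini–Hochberg adjustment over all genes within that sex and a
q < 0.05 call. Genes with zero variance get p = 1. A gene is
phase-specific when it is DE and its mean CPM in one phase strictly
exceeds every other phase (ties specific to neither); it passes the
high fold-change filter when additionally the minimum over other phases
q of log2((mean_p + 1)/(mean_q + 1)) exceeds the threshold (5 for
ovaries, 8 for testes). The pseudo-count of 1 keeps the ratio finite on
zero means; the per-phase minimum (rather than a pooled-mean ratio) is
the stricter of the two readings of "upregulated above the other three
phases" and is the implemented one. A negative-binomial GLM
likelihood-ratio backend was considered and deliberately left out: the
ANOVA path is fully specifiable and calibrates correctly at these
sample sizes (type-I error 0.05 ± 0.02 in the null simulation), and a
moment-based dispersion GLM would add estimator choices without
changing the result surfaces.

## Enrichment

Over-representation of a term in a foreground set of n genes from a
universe of N uses the exact hypergeometric upper tail
P(X ≥ k) with K term genes in the universe, and fold enrichment
(k/n)/(K/N). A term passes when fold > 4 *and* P < 0.05 — both strict,
raw P (no multiple-testing correction on the filter, matching the
filter's definition; a BH column is emitted for information). The
universe is the set of genes carrying at least one term annotation, and
foregrounds are intersected with it before testing. Small random
overlaps (k of 2–3 in a rare term) can pass this filter at roughly the
α level; that is a property of the filter, not a bug.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with defaults mirroring the study design it models:

* **References**: 4 host and 6 symbiont sequences of 100 kb, i.i.d.
  bases at 41.5% / 50.6% GC.
* **Contigs** (500 by default): 250 host, 150 symbiont, 50 unrelated
  ("other", 45% GC), 50 host+symbiont chimeras; lengths uniform
  300–1500 bp; 2% point divergence from the references. Origin
  fragments are allocated *disjointly* on the references, so two
  contigs are near-identical only when planted as duplicates. Ten
  duplicate groups of 2–5 copies carry exactly
  round(0.015 × length) substitutions per copy (identity 98.5% by
  construction, not in expectation), with short 3′ truncations so the
  founder is the longest member. Chimeras are verbatim half/half
  concatenations — they model assembly joints, are recorded with origin
  "ambiguous", and are excluded from accuracy scoring because neither
  class call is wrong for them.
* **Counts**: negative binomial with variance μ + φμ² (φ = 0.1, a
  typical bulk RNA-seq scale), log-normal baselines (median 30, log-sd
  1.3), uniform library factors (0.6–1.4), over 2 sexes × 4 ordered
  phases × 3 colonies. Per sex, 40 genes get a log2 effect of 6
  (females) or 9 (males) in the mature phase — straddling the 5 and 8
  filters — and 20 genes a moderate effect of 3 in the late phase
  (detectable but below the fold filters). Planted genes are drawn from
  genes with baseline mean ≥ 5 so the effect is identifiable above the
  pseudo-count. One sample per sex (middle phase) is an outlier drawn
  from a permutation of the gene baseline profile — depth normalization
  cannot absorb a permuted profile, mirroring whole-sample removal.
* **Terms**: 100 random terms of 10–50 genes plus, per sex, 2 planted
  terms of 30 genes drawing half their members from that sex's strongly
  planted set (realized fold ≥ 6 by construction).

All randomness flows through `numpy.random.default_rng(seed)`; the same
seed reproduces every artifact byte for byte.

**What passing the synthetic benchmark shows — and what it does not.**
The generator plants clean signals: disjoint origins, i.i.d. base
composition, substitution-only divergence, no isoforms, no GC–coverage
coupling, no read-level error model, dispersion constant across genes.
Perfect partition accuracy or exact duplicate recovery on this benchmark
therefore demonstrates the decision rules and thresholds are implemented
correctly, not that real assemblies — with shared ancestral k-mers,
paralogy, chimera gradients and heteroskedastic counts — would separate
this cleanly. Conversely, the expression stage's sensitivity/precision
numbers are driven by the planted effect sizes (6 and 9 log2 units, far
above typical biological effects) and speak to the filter arithmetic,
not to the power of 3-replicate designs in general.

## Problem sizes and runtime

Defaults (500 contigs, 100 kb references, 2000 genes, 24 samples) keep
the full pipeline under ~5 s and the whole test suite under a minute on
one CPU; the dynamic-programming identity is O(len²) per pair and the
greedy clustering relies on the prescreen to stay near-linear at this
scale. Clustering 10⁵+ sequences is out of scope.

## Known limitations

* The semi-global identity is one defensible reading of the clustering
  tools' "identity"; bit-compatibility with any external tool's output
  is not attempted.
* The top-hit tie-break (host before symbiont) is a convention; real
  equal-score ties are rare but their resolution is a coin the package
  deliberately fixes.
* The outlier rule is threshold-based and can flag borderline samples
  in small designs (visible in one example); the guard against
  under-replication bounds the damage.
* Enrichment takes the term map as given — no ontology-graph
  propagation, no parent-term closure.
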