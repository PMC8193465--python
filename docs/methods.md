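# Methods

`cdremir` reconstructs, per phenotype, a bipartite miR–gene co-expression
network from paired expression matrices, classifies *commodore miRs* —
highly connected, non-redundant miR hubs — and characterizes each
commodore's gene neighborhood functionally. This note documents the models,
the numerical choices, and what the synthetic validation does and does not
establish.

## Network model

**Mutual information estimator.** Co-expression between a miR profile
*x* and a gene profile *y* over the *n* samples of one phenotype is scored
by the plug-in (maximum-likelihood) estimate

MI(x, y) = Σᵢⱼ p̂ᵢⱼ log₂ ( p̂ᵢⱼ / (p̂ᵢ· p̂·ⱼ) )

on the joint histogram of equal-frequency bin labels, reported in bits.
The number of bins defaults to ⌊√n⌋ (10 bins at n = 100), a standard
bias/variance compromise for histogram MI; it is configurable. Binning is
rank-based: bin labels depend only on the ordering of values, so the score
is invariant under any strictly monotone transform of either profile —
FPKM versus log-FPKM is immaterial, which removes the usual sensitivity of
co-expression scores to normalization choices. Tied values are always
assigned to a single bin (that of the tie group's smallest rank), so ties
never straddle a bin boundary. Constant profiles cannot be binned and are
removed before scoring (dropped ids are logged).

The plug-in estimator has a known positive bias of roughly
(b−1)²/(2n ln 2) bits for independent inputs (≈ 0.58 bits at b = 10,
n = 100). Because thresholding is purely rank-based, this bias shifts all
scores together and does not affect which pairs become edges.

**Quantile thresholding with ties kept.** With N = (retained miRs) ×
(retained genes) possible links and upper quantile q (default 0.9999), the
threshold is the m-th largest score with m = ⌈(1−q)·N⌉, and *every* pair
scoring ≥ the threshold becomes an edge. No tie-breaking is applied, so a
network can carry slightly more than m edges when several pairs share the
threshold value; this is the mechanism that makes one phenotype's network
marginally larger than the others' in the motivating analysis. ⌈·⌉ is
computed with a 10⁻⁹ slack so that binary representation error in 1−q
cannot inflate the count by one. Nodes with no retained edge stay in the
node sets at degree 0; summaries count connected (k > 0) nodes per layer
and components over non-isolated nodes only. The degenerate case of all
scores equal keeps every pair and emits a warning.

## Commodore classification

For a bipartite node v with degree k ≥ 2, the redundancy coefficient is

rc(v) = |{ {u,w} ⊆ N(v) : ∃ v′ ≠ v, u ∈ N(v′) ∧ w ∈ N(v′) }| / C(k, 2),

the fraction of v's neighbor pairs that would remain co-connected through
some other node if v were removed. rc is undefined (never coerced to a
number) for k < 2, where the denominator vanishes. A **commodore miR** is
a miR-layer node with k ≥ 100 and defined rc ≤ 0.5, both comparisons
inclusive; gene-layer nodes are never classified. Classification is
monotone in both thresholds. A miR can be a commodore in several
phenotypes; records are keyed by (miR, phenotype), and neighborhoods are
compared across records by Jaccard similarity.

## Functional characterization

**Over-representation.** Each commodore neighborhood is tested against
every annotation term with the one-sided hypergeometric tail
P(X ≥ k), evaluated by log-space summation of log-pmf terms (stable down
to the smallest representable p). The universe is the set of annotated
genes among those expressed in the phenotype (after the zero-variance
filter) — the convention of the common enrichment tools; it is
configurable to all expressed genes. Terms with zero universe overlap are
skipped, not assigned p = 1, and excluded from the adjustment family.
Adjustment is Benjamini–Hochberg (configurable to Bonferroni-style via the
underlying multiple-testing routine); significance is adjusted p ≤ 10⁻³.

Because the hypergeometric is discrete, the attainable type-I error at
nominal 0.05 sits slightly below 0.05; the calibration check therefore
uses moderately large terms (100–400 genes of a 2000-gene universe,
query 150) where the null distribution is smooth enough for the attained
rate to be informative (measured ≈ 0.03–0.05 over 2000 term-tests).

**Wang similarity and aggregation.** For enriched terms the Wang semantic
similarity is computed on the ontology DAG with edge contribution weights
w(is_a) = 0.8 and w(part_of) = 0.6 (the convention of the standard GO
semantic-similarity tools; configurable). S-values are computed by dynamic
programming in topological order over the ancestor closure, equivalent to
the max-over-paths product of edge weights. sim(A, A) is exactly 1 by
construction. Terms are clustered by average-linkage agglomeration on
distance 1 − sim and the tree is cut into min(10, #terms) groups; with
fewer terms than groups every term is its own group. Average linkage was
chosen as the common default for semantic-similarity matrices; the linkage
is a parameter. Each group's representative is its member with the lowest
adjusted p, ties broken by raw p, then lexicographic term id; groups are
numbered by ascending representative adjusted p.

## Synthetic cohort (the validation bed)

The generator plants, per synthetic phenotype:

* one **driver** miR sharing a standard-normal latent factor with 120
  disjoint target genes at loading s = 0.9 on the log scale
  (log-expression = s·factor + (1−s)·noise, then exponentiated to an
  FPKM-like skewed positive scale; the monotone link means the rank-based
  MI sees the full dependence, with latent correlation
  s/√(s²+(1−s)²) ≈ 0.99);
* one **redundant trio**: three miRs loaded on one shared factor together
  with a single 120-gene target set, so each member's neighbor pairs are
  covered by its group mates and rc → 1;
* independent log-normal background for everything else. With s = 0 the
  whole layer is background and all transcripts are mutually independent.

Subtype labels are assigned round-robin; each phenotype's factors act only
in its own samples. The toy ontology is a single-rooted random DAG whose
"true" terms annotate exactly the planted target sets; remaining terms
annotate random gene sets (5–200 genes).

**Dimensions.** Defaults are 6000 genes × 1000 miRs × 100 samples per
phenotype. At q = 0.9999 this yields ⌈10⁻⁴·6×10⁶⌉ = 600 edges — the same
~10⁻⁴ edges-to-pairs regime as the motivating breast-cancer networks
(≈ 6.9×10³ edges from ≈ 6.9×10⁷ pairs), and enough room above the 480
planted signal pairs (120 driver + 360 trio) that the driver's full
120-target neighborhood clears the k ≥ 100 gate while ~100+ edges remain
available to background noise. Smaller gene×miR products are incompatible
with the k ≥ 100 commodore definition at this quantile (e.g. 2000×300
pairs cap the whole network at 60 edges), which is why the defaults are
sized as they are.

The recovery study runs 20 seeds of the planted condition and 20 seeds of
pure noise; the end-to-end determinism check uses a scaled-down cohort
(400 genes × 120 miRs × 48 samples, 2 phenotypes, q = 0.997, k_min = 25 —
the gate scaled to the 30-target planted driver), since byte-stability is
size-independent.

**What passing does and does not show.** The generator produces clean
monotone single-factor dependence, no library-size or batch structure, no
count noise, no correlated background, and an ontology with non-overlapping
true terms. Recovery at 100% under these conditions demonstrates the
pipeline's correctness (thresholding, redundancy discrimination,
enrichment wiring), not its power on real tumor expression data, where
signal strength, annotation overlap and confounding are all less
favorable.

## Numerical and degenerate-case choices

* MI is clamped at 0 to absorb −10⁻¹⁶-scale float residue; scores agree
  with an independent plug-in oracle to 10⁻¹² relative tolerance.
* The m-th-largest threshold uses `np.partition` (O(N)); edge extraction
  is a vectorized comparison.
* rc for k < 2 is `None` / NaN in tables; the k ≥ 100 gate means this
  never affects classification.
* Samples present in expression tables but missing from the subtype map
  are excluded with a warning; fewer than 4 samples per phenotype is an
  error (equal-frequency MI needs at least two bins of two).
* All randomness flows from explicit integer seeds; pipeline bundles are
  byte-stable given (parameters, seed, inputs), and the manifest records
  both.

## Known limitations

* The pairwise scoring loop is dense: ~5 s per 6×10⁶-pair network on one
  CPU; very large cohorts would want a blocked or parallel variant.
* rc is computed exactly by neighbor-pair enumeration (O(k²·overlap));
  fine at co-expression degrees, not intended for dense hubs of degree
  10⁴+.
* The enrichment universe convention (annotated ∩ expressed) matters for
  absolute term counts; counts are comparable within a run, not across
  annotation releases.
* The literature-validation stage is deliberately a stub that prints query
  strings; no external service is contacted.
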