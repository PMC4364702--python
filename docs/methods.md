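# Methods

## Scope and model of the data

The pipeline analyzes a set of fungal species, each contributing a gene
registry with functional categories (primary metabolism, SM backbone, SM
clustered, development), secondary-metabolite (SM) gene clusters given as
gene-ID sets, precomputed cross-species orthogroups, all-vs-all protein
similarity hits, two-replicate mutant-vs-WT RNA-seq count matrices, and
GO annotations with an optional term→slim mapping. Orthogroups are the
unit of all conservation logic: a gene family presumed descended from one
ancestral gene, possibly containing within-species inparalogs. No
sequence or genome-coordinate handling is attempted; clusters are sets of
gene identifiers and similarity is consumed as precomputed tabular hits.

## Orthogroup construction

Cross-species orthogroups are an input. Genes absent from them are
treated as species-specific and grouped as follows.

**Hit filtering.** A similarity edge (a, b) exists iff at least one hit
in either direction passes query coverage ≥ 0.60 AND subject coverage
≥ 0.60 (inclusive), e-value < 10⁻⁵ (strict), and percent identity > 60
(strict). Coverage is aligned-span length over sequence length, per side;
when a directed pair has several HSPs only the best-bitscore HSP is
evaluated (no HSP tiling). Edges are unweighted: no weighting scheme is
part of the filtering contract, and the either-direction rule (rather
than reciprocal-best) is the most permissive reading consistent with a
plain coverage/identity cutoff. The coverage bound is inclusive while
identity and e-value are strict, mirroring the usual phrasing of such
cutoffs ("60% coverage", "less than 10⁻⁵", "greater than 60%").

**Markov clustering.** Filtered within-species subgraphs (one per
species; cross-species edges among leftover genes are ignored, since the
cross-species structure is already given by the input orthogroups) are
clustered with a from-scratch MCL: add self-loops (max incident weight,
floored at 1), column-normalize, then alternate expansion (matrix power
2) and inflation (elementwise power, default 2.0, renormalize), pruning
entries below 10⁻⁶, until the maximum absolute entry change falls below
10⁻⁸ or 200 iterations (non-convergence warns and uses the current
matrix). Clusters are read from the limit matrix's attractors;
overlapping attractor systems merge, and a node reachable from several
systems joins the one containing the lowest-sorted node, making the
output a deterministic partition. Connected components are processed
independently (flow never crosses components), which bounds the dense
matrices to component size. On disjoint unions of cliques MCL at
inflation 2 coincides with connected components (oracle-tested), and it
splits two cliques joined by a single bridge. Raising the inflation
tends to fragment clusters further without merging; this monotonicity is
an empirical tendency verified on fixed structured graphs, not a
guarantee — sparse random graphs can violate it.

**Assembly.** Input orthogroups, MCL clusters (as new species-specific
orthogroups), and remaining genes (as singletons) merge into a registry
that provably partitions the gene set; overlap between input orthogroups
and MCL clusters is a hard error.

## SM cluster homology

For clusters a, b from different species, each gene is *matched* when its
orthogroup contains any gene of the other cluster — inparalogs therefore
count, which follows from orthogroups being inparalog-inclusive by
construction. The pair is homologous iff the matched fraction exceeds 1/2
in the larger cluster AND in the smaller one (strict on both sides; equal
sizes treat both clusters as "larger", implemented as max/min of the two
fractions so the score is symmetric). The dual-fraction form is the more
specific of the two natural phrasings of a ">50% of genes are orthologs"
criterion and is the one implemented; whether matched genes of the larger
cluster must *collectively* cover half the smaller one is a coarser
variant we deliberately do not use (each side's fraction is evaluated
independently). Species-specificity is defined on connected components of
the homology graph rather than on pairs, so many-to-one relationships
(two clusters of one species homologous to one cluster of another)
propagate correctly. Link profiles report, for a focal cluster, the
number of its genes whose orthogroup intersects each other cluster,
flagging same-species links as inparalog links.

## Species-specificity statistics

An orthogroup is **strictly** species-specific for a focal species when
it has members in no other species, and **functionally** species-specific
for a category when no other-species member carries that category
annotation; strict implies functional, which the per-category counts
preserve as an invariant. A companion statistic reports the fraction of a
species' SM-cluster orthogroups with no ortholog inside any other
species' SM cluster.

The SM-vs-primary-metabolism contrast uses a 2×2 table
(specific, non-specific) × (SM-category, primary-metabolism) orthogroup
counts in strict mode; orthogroups annotated to both categories count in
the SM column only, avoiding double counting (the overlap policy is a
design choice; the underlying study does not print its table
construction). The two-sided Fisher exact test is authored here: the
p-value sums hypergeometric probabilities of all tables with the observed
margins whose point probability is ≤ the observed one within relative
tolerance 10⁻⁷ (the conventional floating-point tie rule; verified
against exhaustive integer enumeration for every table with margins
≤ 30). Benjamini–Hochberg is the standard step-up with monotonicity
enforcement, applied jointly across all specificity tests of a run.

## Differential expression

The reusable content of this stage is the classification rule and the
downstream accounting, not the estimator: externally fitted DE tables
(gene, log2fc, padj) are accepted unchanged, and the built-in test exists
so synthetic worlds run end-to-end.

* **Normalization** — median-of-ratios: per-sample factor = median over
  genes with all-positive counts of count / per-gene geometric mean;
  total-count scaling (warned) when no such gene exists. Like any
  median-based depth estimate it assumes DE is a minority or roughly
  balanced in direction; heavily one-sided DE biases fold changes toward
  zero by a few percent.
* **Test** — log₂ fold change of normalized condition means with
  pseudocount 0.5; per-gene method-of-moments NB dispersion (pooled over
  conditions on the normalized scale) shrunk two-thirds of the way toward
  a fitted trend α(μ) = a₀ + a₁/μ; Wald statistic from
  Var(K) = μ + αμ² via the delta method. The statistic is referred to a
  t distribution with n₁+n₂−2 residual plus 14 prior degrees of freedom.
  The prior df encodes that the variance is mostly determined by the
  trend (fitted across thousands of genes) rather than the 2 residual
  degrees of freedom; its value was calibrated on null NB simulations
  under the generator's own model so that the p < 0.05 rate is ≈ 5% at
  two replicates per condition — the plain normal reference was
  measurably anti-conservative (≈ 8%) and an unmoderated t(2) had
  essentially no power.
* **Classification** — BH within the tested-gene set (all-zero genes are
  untested and excluded from m); a gene is over-expressed iff adjusted
  P < 0.1 AND log₂FC > 1, under-expressed iff adjusted P < 0.1 AND
  log₂FC < −1, otherwise not_de. All four inequalities are strict, which
  the boundary tests pin down.
* **Summaries** — per-gene-set counts with percentages computed at full
  precision and rounded half-away-from-zero to one decimal, matching the
  reporting convention of knockout-study summary tables.

## Cross-species concordance

Flags are existential ("at least one"), relative to one named partner
species: has_ortholog (any orthogroup member there), has_de_ortholog (any
of them over/under), has_same_direction_ortholog (any sharing the gene's
own class); the three are nested by construction. Percentage denominators
follow the arithmetic of the published chains: "had an ortholog" is a
fraction of the DE-class set; the two DE fractions are of the
ortholog-bearing subset. Orthologous genes present in the partner species
but absent from its expression table count as orthologs with class
not_de. Link tables emit one row per cross-species gene pair sharing an
orthogroup (conflicting when classes differ and at least one is DE); a
per-orthogroup collapsed count is also provided since a plot may draw one
link per pair or per orthogroup.

## GO-slim enrichment

Annotations are collapsed through the term→slim map (identity when
absent; terms without a slim image drop; no ontology-graph propagation
beyond the provided mapping). Each slim term with ≥ 1 background
annotation gets a one-sided upper-tail hypergeometric p-value
P[X ≥ k], BH across the terms of the run, significant at adjusted
P < 0.05. The default background is the annotated portion of the supplied
background set; which reference set (whole annotation vs expressed genes)
an enrichment tool was run with is often unstated, so the caller chooses
the background explicitly.

## Synthetic worlds

The generator emulates the comparative setup at desk scale and is a
deterministic function of its seed.

* **Families** — species subsets drawn from a sharing distribution
  (default: 45% spanning all four species, 12% split over pairs, the rest
  species-specific), one gene per member species plus an inparalog with
  probability 0.08. Default 2,000 genes per species (a few-fold
  down-sampled fungal genome; real genomes carry ~10,000).
* **SM clusters** — default 20 per species (configurable per species),
  sizes uniform on 2–25 (the upper end matching the largest observed
  clusters). Planted conserved pairs use equal-size clusters (default 10
  genes) sharing exactly f·size cross-species orthogroups, so the
  homology criterion detects them iff f > 0.5 by construction;
  non-planted cluster genes draw from species-specific families, except
  that with probability 0.1 a cluster gene joins a cross-species family
  whose foreign members stay outside clusters — emulating recruitment of
  non-clustered genes and exercising the functional-specificity mode.
  Infeasible configurations (planted pairs exceeding cluster counts, SM
  demand exceeding the gene budget, non-integer f·size) fail before
  anything is written.
* **Similarity hits** — within-species inparalog groups emit passing
  pairwise hits (coverage 0.85, identity 70–95, tiny e-values); decoys
  between different groups fail exactly one threshold (identity = 60,
  e-value = 10⁻⁵, or coverage 0.5), so filtering must actively reject
  them; decoys never connect genes of the same group, where the
  best-HSP rule would let them shadow a passing hit. A dropout
  probability deletes within-group hits to model noise: at zero dropout
  pipeline recovery of the planted partition is exact; at dropout 0.3
  the adjusted Rand index stays ≥ 0.95.
* **Counts** — NB with Var = μ + αμ², dispersion α = 0.2, per-sample
  depth factors log-normal(0, 0.1), two replicates per condition (the
  replication level of the emulated design). Baseline means are
  family-level log-normal (median 500 counts, σ = 1, justified by
  20–30M-read libraries over ~10⁴ genes) with per-gene jitter, so
  orthologs are correlated. Knockout targets are drawn per compartment
  (SM cluster, development, other) with regulator-specific fractions
  (defaults emulate a broad VeA-like and a narrow MtfA-like knockout);
  effects are log₂FC ~ Normal(±2, 0.5) (magnitude floored at 0.5)
  applied to mutant means. In the second expressed species, a conserved
  ortholog of a target is itself a same-direction target with
  probability q (default 0.6); only genes without targeted orthologs
  fall back to the independent draw, so the planted copy fraction is
  exactly Bernoulli(q).
* **Annotations** — development families (preferentially fully shared
  ones, emulating the high conservation of developmental genes) carry
  GO:0032502; SM-cluster genes carry the secondary-metabolic-process
  term; filler slim terms are assigned 1–2 per gene, half the time as a
  fine-grained synonym so the slim collapse is exercised.

What passing on these worlds does **not** show about real data: no
sequence evolution (hit structure is planted, not aligned), no gene-order
or synteny signal, dispersion is homogeneous rather than gene-specific,
annotations are noise-free, and the orthogroup "truth" has none of the
ambiguity of real orthology inference.

## Problem sizes and numerical choices

Recovery suites run 20 worlds at the default 4 species × 2,000 genes —
full-pipeline worlds at this scale run in about a second each, keeping
the whole suite comfortably interactive. DE power is reported for planted
effects of magnitude ≥ 2 (the stated effect regime; weaker draws from the
±2 ± 0.5 effect distribution are excluded from the numerator and
denominator both), pooled across worlds. Ties in MCL cluster reading,
table sorts, and all generated identifiers are deterministic;
fold-change pseudocount 0.5; Fisher tie tolerance 10⁻⁷ relative; BH never
reorders its input. Percentages are rounded half-away-from-zero to one
decimal only at the reporting boundary, never internally.

## Known limitations

* The NB test is intentionally simple: no GLM, no per-gene dispersion
  shrinkage with empirical-Bayes weights, no outlier handling, no
  multi-factor designs. For real data, fit externally and feed the table
  through the classifier.
* Median-of-ratios normalization inherits composition bias under heavily
  one-sided DE.
* The homology criterion ignores gene order, orientation, and physical
  distance; it measures shared orthogroup content only.
* Functional-mode specificity trusts the input category annotations;
  annotation gaps in one species inflate apparent functional
  specificity in another.
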