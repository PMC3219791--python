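# Methods

This note documents the statistical models, the synthetic-data
generator, numerical choices, and the limits of what the test suite can
show about real data.

## Count model and differential expression

Counts for gene *g* in lane *i* of a replicate group are modeled as
negative binomial with mean `mu_g` and a single dispersion `phi` shared
across genes, `Var = mu + phi mu^2`; `phi = 0` is the Poisson limit.
`delta = phi/(1+phi)` maps the parameter to [0, 1) for bounded
optimization.

**Dispersion.** `phi` is estimated by maximizing, over `delta`, the
conditional log-likelihood of the within-group counts given each
group's total, summed over genes and over the two groups of the
contrast. Conditioning removes the per-gene means, so a single 1-D
bounded search (Brent, `xatol = 1e-6`) suffices. Genes with zero total
in the contrast lanes are excluded (their conditional likelihood is
constant).

**Exact test.** After joint quantile normalization the library sizes
are equal, so for each gene the group-A sum `Y_A` given the two-group
total `t` has a beta-binomial law `BB(t, n_A/phi, n_B/phi)` (binomial
`(t, n_A/(n_A+n_B))` at `phi = 0`). The two-sided p-value sums the
probabilities of all partitions of `t` whose probability is at most
that observed (relative tolerance 1e-9 for float ties; for equal group
sizes the pmf is symmetrized so mirror partitions are exactly tied, as
they are in exact arithmetic). Normalized counts are rounded to
integers for testing. log2 fold change uses normalized group means with
a pseudo-count of 0.5 per group; a zero-total gene gets `p = 1`,
`log2FC = 0`.

These p-values are discrete: atoms of the conditional law make the
null distribution slightly superuniform, most visibly near `p = 1`.
At the count depths the generator emulates (median ~200 reads per lane,
see below) the atoms are small enough that a 10^4-sample KS test
against uniformity passes at typical seeds; at much shallower depth any
faithful exact test fails that check, which is a property of the test,
not of an implementation.

A historical workflow step sometimes retrieves genes at raw `p < 0.01`
before applying the adjusted-p filter; with BH at 0.05 on the same
p-values that pre-filter is redundant (every gene passing adjusted
`p < 0.05` would pass it whenever more than a handful of genes are
tested), so it is not implemented.

**Filter cascade.** A gene is DE iff (1) median depth >= 2X in at least
one of the two compared groups, where depth = `count * read_length /
exonic_length` and the median runs over the biological replicates of a
tissue/treatment group; (2) `|log2FC| >= 1`; (3) BH-adjusted `p <
0.05`. "At least two uniquely mapped raw counts" for transcriptional
activity is interpreted as summed across all lanes (an any-lane mode is
available). A raw-count depth mode (`depth_mode="raw_count"`) replaces
coverage units where preferred.

**Quantile normalization.** All lanes jointly; each lane's values are
replaced by the cross-lane mean of order statistics at their ranks.
Ties take the mean-order-statistic curve interpolated at the tied
entries' average rank — the dialect of the reference microarray-style
implementation, verified against it on tie-bearing matrices and frozen
into the tests. Under ties no dialect can keep every lane's sorted
vector exactly identical; residual median spread on integer counts is
below 2%.

## Enrichment engines

For a DE list of size `n` (after intersecting with the database
universe, the set of unique genes across all categories), a category of
size `K` in a universe of `N` has `E = nK/N` and

    Z = (O - E) / sqrt(V),
    V = n (K/N)(1 - K/N)(N - n)/(N - 1)   (hypergeometric, default)
    V = E                                  (Poisson option)

with the one-sided normal upper tail as the Z-based p and the exact
hypergeometric upper tail alongside. Significance requires `Z >= 2`,
`p <= 0.05` and `E > 1`; for cis-element enrichment the p entering the
rule is the BH-adjusted hypergeometric tail. Degenerate configurations
(`V = 0`) are flagged and never significant. Gene ids matching the
unplaced-scaffold pattern (`Sb###s######`) are removed when loading any
category database.

## Length-aware GO enrichment

Transcript length inflates the power to call a gene DE, so categories
of long genes are overcalled by central tests. The probability
weighting function (PWF) is fitted as binned DE proportions (20
equal-occupancy length bins) smoothed by weighted isotonic regression
(non-decreasing in length), evaluated by linear interpolation and
clamped to `(1e-4, 1 - 1e-4)`. Per category,
`omega = mean PWF(members) / mean PWF(non-members)`, and the p-value is
the upper tail of the Wallenius noncentral hypergeometric law.

The Wallenius pmf is evaluated by the exact recursion of the
sequential-urn process (the state distribution over reds drawn is
propagated across the `n` draws; O(nK) work, float-exact). The
classical integral representation was found numerically delicate at
large odds and is not used; an independent sequential-urn Monte-Carlo
sampler cross-checks the recursion in tests. GO pairs are deduplicated
on load, gene-model `.N` suffixes are collapsed, and significance is
called on the raw Wallenius p (`p <= 0.05`), with BH-adjusted values
reported alongside.

## Pathway networks

Reaction coverage is `|reactions with >= 1 DE gene| / |reactions|`,
reported only for pathways with >= 3 reactions. Related pathway
variants are merged by a collapse map (member sets become unions;
chains resolve; cycles are rejected). In the cross-talk graph, nodes
are collapsed pathways containing >= 1 DE gene, scored
`(#up - #down)`; edges join pathways sharing >= 1 DE gene (a gene
counts once per pair regardless of reaction multiplicity) with weight
classes `<=5`, `6-9`, `>=10`. The hormone subgraph keeps every node on
any unweighted (hop-count) shortest path between any pair of
hormone-flagged pathways, ties included, hormone nodes always retained;
a 1-hop-neighborhood mode is also provided since figure-style
renderings sometimes include direct neighbors.

## Promoter scanning

Upstream windows (default 1000 bp) anchor at the gene feature start
(configurable), truncate at contig edges, and are oriented 5'->3'
toward the gene; minus-strand windows are reverse-complemented. IUPAC
codes expand to base sets; an `N` in the genome matches nothing
(masked sequence cannot create hits). All overlapping matches on both
strands are recorded (single-strand mode available); positions are
1-based from the window's 5' end with distance-to-gene-start derived.
Enrichment uses gene-level presence, so repeated hits within one
promoter never inflate the observed count.

## Ortholog triage

Unknown function = case-insensitive whole-word match of a description
against {hypothetical, expressed, predicted, uncharacterized}
(whole-word so that "overexpressed" does not match). The decision tree
runs once per non-focal species: keep a DE, unknown-function focal gene
iff it has >= 1 ortholog in the species, all its orthologs there are
unknown-function, and >= 1 is on the species' published
drought-responsive list. Expression direction is deliberately ignored.
A stricter mode requires all-unknown orthologs in every species
simultaneously.

## Synthetic-data generator

The generator emulates the study design: 2 tissues x 2
treatment/control pairs x 3 biological replicates (24 lanes). Defaults
are the emulated conditions:

- baseline means log-normal with median 200 counts/lane (sdlog 1),
  calibrated to the study's reported count marginals (~40-50% of
  expressed genes in the 5,001-50,000 total-read decade, >80% above 500
  total reads);
- common dispersion `phi = 0.1`, a typical bulk-RNA-seq value for
  biological replicates;
- 17% of genes silent everywhere (the study's inactive fraction);
- 5% of genes spiked, log2FC in {±1, ±2}, each in one contrast
  (options pin all spikes to one contrast and/or fix the spiked genes'
  baseline mean for controlled recovery experiments);
- exonic lengths log-normal, median 1.2 kb, floor 200 bp; read length
  50 bp;
- run 3 scaled x1.3, mimicking the mid-study base-caller upgrade that
  quantile normalization must remove;
- planted enriched pathway/GO/TF categories (odds 5 by default) drawn
  at the large end of their size ranges so the `E > 1` gate cannot mask
  a planted signal by construction; scaffold-pattern decoy ids are
  inserted to exercise loader filtering;
- ABRE and DRE instances planted at recorded positions, preferentially
  in DE-gene promoters; a 10-contig genome laid out so extraction
  round-trips exactly on both strands;
- a planted conserved-unknown ortholog set plus one decoy per decision
  branch (annotated ortholog, no drought hit, annotated focal gene,
  non-DE focal gene).

One global seed; every sub-generator derives a child seed, so fixed
seed means bit-identical outputs.

What the generator does **not** emulate: gene-gene correlation,
GC/positional bias, tagwise dispersion, isoforms and splice junctions,
ortholog inference errors, and real ontology structure (GO terms are
flat labels). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real libraries.

## Problem sizes and experiment designs used in verification

Null calibration uses 10^4 genes (3 vs 3, `phi = 0.1`); the spike-in
experiment uses 200 genes spiked at |log2FC| = 2 with baseline mean 50
inside a median-50 background, constant 625-bp lengths (so mean 50
corresponds to ~4X coverage and the depth gate reflects expression
rather than random length clipping), equal library sizes, and no
quantile normalization — isolating the filter cascade. That isolation
matters: 200 spikes concentrated in one contrast's treatment lanes
violate quantile normalization's equal-distribution assumption and get
their fold changes compressed (down-spikes from |log2FC| 2 to ~1.6),
a genuine property of normalize-then-test pipelines worth knowing when
interpreting real designs with strongly asymmetric response. Scanner
equivalence uses 10^3 random 1-kb promoters x 20 random degenerate
motifs; network oracles use 50-pathway databases and 10-node toys;
determinism runs the full pipeline twice at 2,000 genes. Observed
spike-in FDP fluctuates around the BH-controlled expectation (0.02-0.07
across seeds), as it must.

## Known limitations

- The exact test is implemented for equalized library sizes only;
  unequal sizes are handled by normalizing first, not by offset terms.
- Only a common dispersion is estimated (no tagwise/trended shrinkage,
  no GLM designs or batch covariates).
- GO annotations are used as given; no ancestor propagation up the
  ontology graph.
- The cis-element scanner is pattern matching, not PWM scoring.
- Wallenius evaluation is exact but O(nK) per category; for category
  sizes in the tens of thousands an asymptotic approximation would be
  preferable.
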