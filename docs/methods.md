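# Methods

## Overview

`comorbnet` compares two disease-associated gene sets over one weighted
interactome. All analysis stages are deterministic functions of their
inputs; randomness exists only in the synthetic-data generators, each a
pure function of a spec containing its own seed.

## Network construction

Raw edge records (STRING-links-style, scores 0–1000, or generic TSV with
scores already in [0, 1]) are canonicalized in one pass: scores divided by
the dialect's scale, self-loops dropped, duplicate and reciprocal records
collapsed keeping the maximum score, edges below `score_min` removed, and
nodes left without any surviving edge removed entirely. Dropping isolates
is deliberate: a submitted gene list generally yields a smaller network
because some genes have no retained interaction, which is how a shared gene
set larger than the resulting network arises in practice. Disease networks
are induced subgraphs of the one supplied interactome rather than
separately retrieved networks — this removes any live-database dependency
while preserving the comparison logic; the `score_min` cutoff is a required
config value because no single default is defensible across interactome
releases.

## Centrality and role calls

Degree ignores edge weights (an edge is an interaction regardless of
confidence). Betweenness is Brandes' algorithm on unweighted shortest
paths with fractional credit across equal-length paths, normalized by
2/((n−1)(n−2)) for n ≥ 3 and defined as 0 for smaller networks; it is
computed over the whole graph, so node pairs in different components
simply contribute nothing. Hubs are nodes with degree strictly above
mean + `k_sd`·SD (`k_sd` default 2). SD is the population form
(divide by n) — the NetworkAnalyzer convention — with a `ddof` switch to
the sample form; the strict inequality means regular graphs have no hubs.
Bottlenecks are the top ceil(`fraction`·n) nodes by betweenness
(`fraction` default 0.05), ranked descending with lexicographic
tie-break for determinism. The ceiling is evaluated as
ceil(fraction·n − 1e-9) because IEEE arithmetic pushes products like
0.05·100 marginally above the exact integer, which would otherwise inflate
the count by one. Hub-bottlenecks are the intersection; key genes are the
union of the common network's hubs and bottlenecks, carrying provenance
flags for membership in the cross-network shared hub/bottleneck sets (the
subset relationship seen in the motivating analysis is reported, never
assumed).

## Cohesive complex detection

Cluster quality is cohesiveness f(S) = w_in/(w_in + w_bound + p·|S|), with
w_in the total internal edge weight, w_bound the boundary weight and p the
node penalty. Growth is greedy local search from a seed: the single best
boundary addition or non-seed removal that strictly increases f, ties to
the lexicographically smallest gene; strict increase on a finite state
space guarantees termination. Swaps are not considered — the simplest move
set consistent with the method's description; exhaustive small-graph
oracles in the test suite bound the cost of that choice. Seeds are
uncovered nodes in decreasing degree order. Grown sets merge when
ω(A,B) = |A∩B|²/(|A||B|) ≥ `overlap_threshold`, unioned to a fixpoint;
at the default threshold of 1 only identical sets merge. The haircut rule
iteratively removes members whose internal incident weight is below
`haircut_threshold`·(2·w_in/|S|) (a no-op at the default 0). Clusters
below `min_size` (default 3, the conventional smallest non-degenerate
complex; not stated by the motivating analysis) are dropped.

Significance is a one-sided Mann–Whitney U test that members' in-weights
exceed their out-weights: exact enumeration of all C(2m, m) group
assignments of the combined midranked multiset when the cluster has ≤ 8
members, tie-corrected normal approximation (scipy) otherwise; the two
branches agree within 0.02 on random length-8 inputs in the test suite.
The p-value is descriptive and not corrected across clusters, matching how
such per-cluster values are conventionally reported.

A structural property worth knowing: with zero node penalty, a degree-one
node attached to a cluster always increases cohesiveness (its absorption
converts a boundary edge into an internal one at no cost), so detected
clusters include the pendant fringe of a dense module. This is faithful to
the cohesiveness objective, not an artifact.

## Enrichment and term grouping

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) (scipy's stable implementation) with the universe defaulting to
the annotation database's genes intersected with the interactome nodes —
the background an interactome-projected analysis actually searches; the
motivating analysis never defines its background, so this is configurable.
Terms need at least `min_genes` = 2 query hits to be tested (single-gene
hits are uninformative and conventionally excluded). Correction is
Benjamini–Hochberg by default, with Bonferroni and Holm step-down
(`bonferroni_stepdown`) available since grouping tools often default to
the latter.

Term relatedness is Cohen's kappa of the two terms' gene memberships over
the universe's 2×2 agreement table, with identical sets defined as κ = 1
(covering the degenerate p_e = 1 case). Grouping links terms with
κ ≥ `kappa_threshold` (default 0.4, the grouping tool convention), seeds a
group from each term's closed neighborhood, and iteratively merges groups
sharing ≥ 50% of the smaller group's terms. A term can end in several
final groups — mirroring how a pathway may appear in more than one printed
group. Group ids are 0-based by best member p-value; each group is labeled
by that best term.

## Synthetic data

The generators emulate the study's input shapes at desk scale:

- **Disease pairs**: exact sizes and intersection (defaults 838/331/113 in
  a 2 000-gene universe, the scale of the motivating comparison), sampled
  without replacement.
- **Interactomes**: planted-partition graphs — Bernoulli(p_in) within
  planted modules, Bernoulli(p_out) elsewhere — plus optional planted hubs
  (extra nodes wired to a configurable number of partners, preferentially
  outside modules so module density and hub degree stay independently
  tunable) and an optional two-clique bridge motif whose middle node has
  raw betweenness exactly clique_size², strictly the graph's maximum.
  Edge weights are 1.0 by default, with an optional uniform(0.4, 1.0)
  model mimicking scaled STRING combined scores, since the motivating
  analysis never states whether edges were weighted.
- **Annotations**: uniform background terms plus planted terms drawing a
  configured fraction of their genes from a ground-truth target set.

The clustering benchmark (`make_clustering_benchmark`) uses two 20-node
modules at p_in = 0.95 with a 20-node background fringe at p_out = 0.005 —
the classic community-recovery regime where modules dominate the graph.
Because of the satellite-absorption property above, a much larger sparse
background dilutes Jaccard-based recovery scores without making modules
less detectable; the benchmark therefore measures recovery where the
metric is meaningful. The end-to-end benchmark
(`make_benchmark_scenario`) builds a 153-node interactome (150 background
nodes incl. one 20-node module, 3 hubs of planted degree 40) and two
123-gene disease lists sharing the module and hubs plus disease-specific
background samples.

What the generators do not emulate: real degree distributions (no
scale-free tail beyond the planted hubs), correlated annotation structure,
identifier noise, or literature bias in gene–disease associations.
Passing the planted-recovery tests shows the algorithms recover the
structure they target under their stated assumptions — not that any
particular real-data result is correct.

## Determinism and numerical choices

Every writer sorts its rows and formats floats to 6 significant digits, so
identical inputs give byte-identical files; logs omit timestamps for the
same reason. Greedy growth uses a 1e-12 tolerance for "strict increase"
and tie comparisons. All generator randomness flows from
`numpy.random.default_rng(seed)`; analysis stages take no seed at all.
Degenerate inputs degrade gracefully: an empty common gene set produces a
complete report with empty downstream sections and a warning, ≤ 2-node
networks have betweenness 0, and a single-node network is its own
(degenerate) bottleneck since ceil(0.05·1) = 1.

## Problem sizes

Test and benchmark sizes are chosen so exhaustive oracles stay exact and
replicated simulations stay cheap: betweenness is cross-checked against
full shortest-path enumeration on all 995 non-isomorphic connected graphs
of ≤ 7 nodes plus 50 random 8-node graphs; the hypergeometric tail against
complete draw enumeration for all N ≤ 12 configurations; recovery rates
over 20 seeded replicates; null calibration over 50 seeds × 200 terms.

## Known limitations

- The published networks themselves (99 nodes/333 edges, specific hub
  identities, printed adjusted p-values) depend on unversioned 2017
  database snapshots and are treated as documented behavior: the bundled
  transcriptions exercise the downstream logic, they are not recomputation
  targets.
- The source tables are internally inconsistent about the fifth
  common-network bottleneck (TLR2 vs TLR4 in different passages); the
  transcription follows the printed table, and the pipeline only ever
  reports computed results.
- Greedy cohesiveness growth finds local optima; global optimality is
  checked only on small graphs by exhaustive oracles.
- Betweenness is unweighted; weighted-shortest-path centrality, directed
  networks and other centralities (closeness, eigenvector) are out of
  scope.
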