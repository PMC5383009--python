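# Methods

This note records the models, conventions and numerical choices behind
netkit, and what the synthetic benchmarks do and do not establish about
real interactome data.

## Network model and curation

Networks are simple undirected graphs over UniProtKB accessions. Edges are
unweighted: interaction-confidence scores present in MITAB exports are
ignored, since the analyses here (path lengths, centralities, MCL on a 0/1
adjacency) treat every supported interaction equally.

MITAB 2.5 parsing takes the **first alternative** of each identifier
column and the first taxon entry; isoform suffixes (`P05067-2`) collapse
to the parent accession by default because node counts in interactome
studies are per protein precursor (disable with `collapse_isoforms=False`
/ `--keep-isoforms`). MITAB 2.5 carries no interactor-type columns;
protein detection therefore keys on the `uniprotkb` identifier namespace,
with the type CV read opportunistically when a wider (2.7-style) row
provides it.

Curation order is fixed: **non-human → non-protein → self-loop →
duplicate**, and a row failing several filters is counted once in the
first failing class, which makes removal reports unambiguous and
permutation-stable. A row is non-human unless *both* taxa equal the human
taxon (9606): mixed-taxon and missing-taxon rows are removed, because a
row that cannot be confirmed human–human does not belong in a human
interactome. The canonical edge key is the lexicographically sorted
accession pair, so swapped interactor columns deduplicate deterministically.

Seed expansion is two-step: edges incident to at least one seed define the
node set V1, then all edges with both endpoints in V1 are added. Nodes
appearing only in self-interaction rows can never enter V1; the filter
report counts them separately (`selfonly_nodes_removed`) together with
both the post-seed-step and final node/edge counts, so either reading of
how a node-count drop decomposes can be audited.

## Topology conventions

- **CPL** is the mean shortest-path hop count over *connected* unordered
  pairs; disconnected pairs are excluded rather than treated as infinite
  (the NetworkAnalyzer convention), so a single CPL is defined for
  networks that contain small satellite components. When no connected
  pair exists the sentinel is NaN. Distances come from
  `scipy.sparse.csgraph` BFS, which keeps removal trajectories cheap.
- **Local clustering** for degree < 2 is defined as 0 and included in the
  network mean by default. Published means rarely state their convention;
  `exclude_low_degree=True` gives the other one.
- **Betweenness** is Brandes shortest-path betweenness with even splitting
  over equal-length paths, reported raw and normalised by
  $(n-1)(n-2)/2$; normalisation cannot change rank order.
- Ties everywhere (component choice, top-N cutoffs, attack order) break by
  accession sort, so outputs are bit-stable.

## Power-law fitting

The default estimator is ordinary least squares of $\log_{10}$ value on
$\log_{10} k$ over positive-count bins, with $a = 10^{\text{intercept}}$
and $\gamma = -\text{slope}$. This is the estimator behind the
interactome literature's published $P(k) = a k^{-\gamma}$ fits, which is
why it is the default; it is known to be biased on sparse tails, and a
discrete maximum-likelihood alternative (`method="mle"`, Clauset-style
$\hat\gamma = 1 + n / \sum \ln(k_i/(k_{\min}-0.5))$) is provided for
sensitivity analysis. Zero-count degrees are necessarily excluded (log
undefined); fits require at least three usable points.

The exponent-recovery benchmark samples 5000 draws from an exact bounded
discrete power law ($\gamma = 1.5$, $k \in [1, 50]$). The bounds are
chosen so every bin has non-trivial expected count, the regime in which
log-log OLS is a consistent estimator of the exponent; recovery within
±0.1 holds across seeds.

## Null model and small-world verdict

The null is the uniform random graph $G(n, m)$ with exactly the observed
node and edge counts, replicated (default 100 draws) — a single draw, as
used in some published comparisons, is statistically fragile. The
operational small-world verdict is `cc_observed > cc_mean` **and**
`cpl_observed ≤ cpl_mean + 2·cpl_sd`; the literature usually states this
comparison only verbally. Note that the expected clustering of $G(n,m)$
is approximately the edge density $2m/(n(n-1))$; published null-model CC
values well below that density cannot come from this model, so netkit
reports its own null statistics and does not attempt to match such
figures. A degree-preserving rewiring null is a documented non-goal.

## Lethality test

Attack order is computed **once on the intact network** (static policy) —
"removal in descending order of centrality" reads most naturally as a
fixed order — with `ranking_policy="recomputed"` available since
re-ranking after each removal is a plausible alternative reading. Failure
trajectories average per-seed CPL curves with a per-step standard
deviation. When removal disconnects the graph, CPL continues over the
remaining connected pairs (consistent with the CPL convention above)
instead of jumping to infinity; if no connected pair remains the
trajectory records the NaN sentinel and truncates. Defaults: removal up
to 20% of nodes, one node per recorded step; both configurable. The
benchmark uses 300-node preferential-attachment graphs with 20 failure
seeds and 10% removal — large enough for a stable direction of the
attack-vs-failure contrast, small enough to run in seconds.

## MCL

The transition matrix is column-stochastic adjacency with a self-loop
weight of 1 on the diagonal (standard MCL practice, configurable);
iterations alternate expansion (matrix power 2) and inflation (entrywise
power $r$, column renormalisation), followed by pruning of entries below
$10^{-5}$ and renormalisation, until the max-norm change falls below
$10^{-8}$ or 100 iterations. Iteration is dense `numpy`: at interactome
scale (≤ a few thousand nodes) dense matrix powers are simpler and fast
enough that sparse machinery isn't warranted.

Clusters come from the limit matrix's attractors (nodes with positive
diagonal). Attractors linked by direct flow form one attractor system; a
node drawing flow from several systems — the classic symmetric-overlap
case, e.g. a node equidistant between two modules — is assigned to the
system receiving the largest share of its column mass, ties to the system
with the smallest representative. This yields a deterministic partition
(disjoint, covering), and flow cannot cross connected components, so
components are never merged. Non-convergence returns the current
partition flagged `converged=False` rather than raising.

Default inflation is 1.8, the customary setting for biological networks;
`inflation_sweep` reproduces the granularity-vs-inflation table over
1.8–3.0. Exact replication of any particular GUI tool's cluster count is
not a goal: self-loop and pruning defaults differ across
implementations.

## Enrichment

The test is the exact hypergeometric upper tail via `scipy.stats
.hypergeom.sf`; BH adjustment is the step-up definition implemented
directly (cross-checked against statsmodels in the tests). Terms with
$k = 0$ in the study set are excluded from the BH family (they cannot be
over-represented; this reduces the multiplicity burden). The
`min_drivers` filter (default 3) applies to the significance verdict, not
the testing, so small-driver terms remain inspectable in the output with
their p-values. The default background is the annotated proteins of the
analysed network (network-as-reference); an explicit background
collection switches to whole-annotation mode — which one a published GUI
run used is often unstated, so neither is asserted. Two preset alphas
(0.05 and 0.01) mirror common tool profiles. True-path propagation
handles is-a parents only; full ontology semantics are out of scope.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure the analysis assumes*:
a connected heavy-tailed graph (preferential attachment; configuration
model behind a flag), planted dense modules (per-pair Bernoulli
within/between rates), planted over-represented terms (independent
per-pair annotation at a background rate, boosted on term–module pairs),
and MITAB contamination in four pairwise-disjoint removable classes so the
expected filter report is exact. Fixed seeds give byte-identical files.

It does **not** emulate: study bias (hub degree inflated by publication
volume), spoke-expanded complexes, confidence-score heterogeneity,
inter-database identifier drift, or correlated annotations along the
ontology. Passing the round-trip and recovery benchmarks therefore shows
the *pipeline machinery* is correct under its stated assumptions — not
that any particular biological claim holds on a live database snapshot.
Snapshot-dependent published figures (node/edge counts, specific hub
lists, specific cluster structure) can be regenerated only against the
corresponding database export; the pipeline accepts such an export
directly (`netkit run --config …` pointing at the downloaded MITAB file).

## Problem sizes used in the test and acceptance runs

Oracle-equivalence checks run on the complete graph atlas (every graph on
≤ 7 nodes) plus seeded random 8- and ≤ 12-node graphs, where exhaustive
shortest-path enumeration is tractable. Calibration uses 200 simulated
study sets over a 200-protein, 50-term annotation model. MCL agreement
uses 50 random graphs of 10–40 nodes against an independently coded
reference implementation with identical conventions. These sizes were
chosen so the full suite completes in well under a minute while keeping
every Monte-Carlo bound at three standard errors.
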