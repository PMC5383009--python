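# netkit

Seed-expanded protein–protein interaction (PPI) network assembly and
analysis, built around the workflow used to chart the **human amyloid
interactome**: start from a curated list of amyloid-forming precursor
proteins, pull their experimentally supported interactions from a PSI-MITAB
2.5 export, clean the records with explicit curation rules, and
characterise the resulting graph — topology, null-model comparison,
hubs/bottlenecks, robustness under attack and failure, Markov clustering,
and term over-representation.

It is intended for systems biologists who want a reproducible, scriptable
version of the Cytoscape-style interactome protocol, and for method
developers who need a benchmarkable implementation with synthetic ground
truth.

## What it computes

For a simple undirected network with $n$ nodes and $m$ edges:

- **density** $d = 2m / (n(n-1))$, **clustering coefficient** $CC$ (mean
  local transitivity), **characteristic path length** $CPL$ (mean
  shortest-path hop count over connected pairs);
- a **degree-distribution power-law fit** $P(k) = a\,k^{-\gamma}$ by
  log-log least squares (the NetworkAnalyzer convention; discrete MLE
  available behind a flag), plus the clustering-per-degree scaling
  $C(k) \sim k^{-\gamma_c}$;
- a replicated **uniform $G(n,m)$ null model** and an operational
  small-world verdict ($CC$ above the null mean, $CPL$ within two null
  standard deviations);
- **hubs** (top-$N$ degree) and **bottlenecks** (top-$N$ betweenness
  centrality, equal-length shortest paths split evenly);
- a **lethality test**: CPL and giant-component trajectories under random
  node removal ("failure", averaged over seeds) versus removal in
  descending degree or betweenness order ("attack");
- **Markov clustering (MCL)**, implemented from scratch on dense matrices
  (expansion $e=2$, inflation $r=1.8$ by default, threshold pruning), with
  the customary "keep clusters of three or more proteins" filter;
- **hypergeometric over-representation** of annotation terms
  ($p = P[X \ge k]$, $X \sim \mathrm{Hypergeom}(N, K, n)$) with
  Benjamini–Hochberg adjustment, true-path propagation over an optional
  term hierarchy, and a minimum-driver filter (terms carried by fewer than
  three study proteins are never called significant).

The curation rules for MITAB input are: keep human–human rows only, keep
protein (`uniprotkb:`) interactors only, drop self-loops, collapse
duplicate rows (including swapped interactor columns) onto canonical
unordered pairs, then seed-expand: keep edges touching a seed protein and
all edges among the nodes so collected. Proteins whose only records are
self-interactions never enter the network. The 28 in-vivo amyloid
precursor seeds and the 13 in-vitro/amyloid-related proteins ship as
packaged tables (`netkit.mitab_io.load_seed_proteins()`).

A first-class synthetic-data module (`netkit.synthetic_data`) generates
scale-free networks, planted-partition graphs, annotation tables with
planted enriched terms, and MITAB files salted with a known number of
removable contaminant rows — so every stage of the pipeline can be
verified offline against ground truth.

## Worked example

Generate a synthetic interactome export with known contamination, curate
it, and analyse the result:

```python
from netkit import synthetic_data as sd, mitab_io, graph_core as gc, topology, mcl_clustering as mcl

g = sd.generate_scale_free(120, 2, seed=42)
spec = sd.ContaminationSpec(n_nonhuman_rows=4, n_chemical_rows=3,
                            n_selfloop_rows=2, n_duplicate_rows=5)
sd.write_mitab(g, spec, 42, "demo.mitab")

net, report = mitab_io.run_curation("demo.mitab", sorted(g.nodes))
summary = gc.summarize(net)
fit = topology.fit_power_law(
    {float(k): float(c) for k, c in summary.degree_histogram.items()})
```

This prints (via the fields of `report`, `summary` and `fit`):

```
rows read:           250
non-human removed:   4
non-protein removed: 3
self-loops removed:  2
duplicates removed:  5
final network:       120 nodes, 236 edges
density = 0.0331  CC = 0.1703  CPL = 2.9183
degree fit: P(k) = 66.492k^-1.39291  regime: hub-dominated
null CC = 0.0311 +/- 0.0128  null CPL = 3.5743 +/- 0.0540  small_world: True
MCL clusters: 14 sizes: [45, 19, 8, 8, 7, 6, 6, 4] ...
```

Reading: the curation filters removed exactly the 14 planted contaminant
rows and recovered the clean 120-node, 236-edge graph. The network is
sparse (density 0.033), far more clustered than its size-matched random
null (0.170 vs 0.031) with *shorter* paths (2.92 vs 3.57), hence
small-world; the degree fit's exponent below 2 marks a hub-dominated,
scale-free-like topology; MCL at inflation 1.8 partitions it into 14
clusters dominated by one 45-node module.

The same steps are available from the shell:

```bash
netkit simulate --n 120 --seed 42 --out demo.mitab
netkit assemble --mitab demo.mitab --seeds seeds.txt --out network.tsv
netkit topology --graph network.tsv --null-reps 50 --seed 42
netkit cluster  --graph network.tsv --inflation 1.8
netkit lethality --graph network.tsv --mode all --seeds 1:20
netkit run --config study.yaml        # full pipeline, writes report.json
```

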