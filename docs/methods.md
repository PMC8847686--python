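# Methods

## Screening model

The package screens for proteins that are simultaneously (i) reachable
within one interaction from both a drug's predicted targets and a disease's
known targets and (ii) topologically central in the shared neighborhood.
The underlying assumptions are those of network pharmacology: the
interactome is a single undirected, unweighted simple graph; a compound's
action propagates to direct interactors of its targets; and proteins that
sit in the dense, central part of the drug–disease shared subnetwork are the
most plausible mediators of the therapeutic effect.

Seed expansion is exactly one hop (seeds + direct interactors + induced
edges). Deeper expansions grow subnetworks toward the whole interactome and
drown the intersection signal; one hop is also the only expansion depth
consistent with typical seed-to-subnetwork growth ratios in this kind of
study (on the order of 10² seeds growing to a few 10³ nodes). The hop count
is nonetheless an explicit function argument rather than a constant.

Intersection follows merge-intersection semantics: common nodes *and*
common edges, with nodes isolated by the edge intersection retained. Keeping
isolates matters because the next stage thresholds on the *median* degree:
dropping them would silently raise the median and tighten the hit-hub cut.

## The two-stage cascade and the median scope

Stage 1 keeps nodes with degree strictly greater than twice the median
degree of the intersection network ("hit hubs"). Stage 2 recomputes five
metrics — degree, unnormalized betweenness, per-component closeness,
neighborhood connectivity, local average connectivity — and keeps nodes
strictly above the median of every one of them simultaneously. Strict
inequalities are used throughout; a vertex-transitive network therefore
screens to nothing, which is the intended degenerate behavior.

Where the stage-2 medians are taken is a genuine design choice:

* `median_scope: stage` (default): metrics and medians on the hit-hub
  network itself. This is the natural reading of per-stage recomputation and
  matches the survivor ratios such cascades typically report (roughly an
  order of magnitude from hit hubs to core).
* `median_scope: intersection`: metrics and medians on the full
  intersection network, with the cuts applied to hit-hub nodes.

The two scopes answer different questions. Stage scope ranks hubs *against
each other* and is appropriate when the hit-hub set is large and
heterogeneous. But it self-competes when the candidate set is small and
already dominated by a single dense module: the medians are then medians *of
the module*, each strict cut discards about half of it, and betweenness —
which is low inside a dense, redundantly connected module — discards a
nearly independent half, so the joint survivor set collapses regardless of
how cleanly the module was planted. In the synthetic validation study
(below), where ~30 of ~45 hit hubs are the planted core, stage scope
recovers only ~20% of the core while intersection scope recovers >90% with
precision >90%. The planted-core validation therefore runs with
`median_scope: intersection`; a regression test documents the stage-scope
self-competition cap. For real screens with hundreds of hit hubs the
default stage scope is the appropriate choice.

A related, intended property: the cascade is *not* idempotent. Each stage's
medians are functions of that stage's input network, so re-running a filter
on its own output applies new, stricter thresholds (a lone surviving hub
cannot exceed twice its own median degree). A regression test pins this
down.

## Centrality conventions

* Betweenness: Brandes' algorithm, unnormalized, each unordered endpoint
  pair counted once. On C4 every node scores 0.5.
* Closeness: (c−1)/Σd within each connected component, so values stay in
  (0, 1] on disconnected graphs and a K2 component scores 1.0.
* Neighborhood connectivity: mean degree of the node's neighbors in the
  analysed graph.
* Local average connectivity: mean, over the node's neighbors, of their
  degree inside the subgraph induced by those neighbors; bounded by
  degree − 1.
* Every metric of a degree-0 node is 0, so medians over networks with
  isolates are well defined.
* All accumulations run in sorted node order; outputs are bit-reproducible.

Exact brute-force oracles (exhaustive shortest-path enumeration over a
hand-written BFS; direct-definition closeness/NC/LAC) live in the test
suite and agree with the implementations to 1e-9 on random graphs.

## Enrichment

The over-representation p-value is the hypergeometric upper tail
P[X ≥ k] with X ~ Hypergeom(N, K, n); it is computed through scipy's
log-space survival function and agrees with exact rational enumeration to
better than 1e-12 relative error over the full lattice N ≤ 40. Terms with
zero query overlap are excluded before correction (only representable terms
are tested); an option includes them. BH step-up q-values are computed
within each term namespace independently, mirroring per-ontology analyses;
the namespace is the `namespace|description` prefix of the GMT description
field, with un-prefixed terms sharing one namespace. The background defaults
to the union of term members in the GMT and should normally be overridden
with the interactome node set, which is what the pipeline does.

## Synthetic-data generator

The generator emulates the inputs such a screen consumes, with planted
ground truth:

* **Interactome**: Barabási–Albert preferential attachment (default
  n = 500 proteins, m = 3 edges per new node) giving the right-skewed,
  hub-dominated degree distribution the hit-hub stage assumes, followed by
  densification of a randomly chosen core module (default 30 nodes) by
  adding missing core–core edges until the induced density reaches the
  target (default 0.8). Scale-freeness here is a modeling choice — real
  curated interactomes are only approximately scale-free.
* **Seed sets**: two independent sets (default 40 + 40) drawn 80% from the
  core-adjacent pool (core nodes and their direct neighbors, uniformly) and
  20% from the remaining nodes, emulating target lists that partially tag
  the shared disease module.
* **Annotation terms**: 200 terms with sizes uniform on [10, 30]; five
  planted terms draw ≥90% of their members from the core, the rest draw
  uniformly from all nodes. The term-size band is a realistic pathway-size
  range whose upper end keeps planted terms constructible
  (0.9 × 30 ≤ core size).

What the generator does **not** model: edge confidence scores, direction,
tissue specificity, identifier-vocabulary noise, or the literature biases of
curated databases. Passing the validation study shows the pipeline recovers
a planted dense module under idealized topology; it does not certify
performance on any specific curated interactome snapshot.

Randomness: one integer seed; each generator operation derives its own
numpy generator via a fixed SeedSequence spawn key, so every output is a
pure function of the configuration and independent of the order in which
the operations are called. Identifiers are zero-padded (`P0001`, `T0001`)
and all writers sort, so textual outputs are diff-stable.

## Validation study sizes

The validation suite and `scripts/acceptance.py` use: 50 random graphs of
≤ 10 nodes for the centrality oracles; the full (N ≤ 40) grid for the
hypergeometric check (the script samples N ≤ 25, ~44k tuples); 1000 random
vectors for BH; 100 simulated screen pairs at n = 150 for cascade nesting;
20 seeded studies at n = 500 for planted-core recovery and enrichment
power; 200 null studies for FDR control. These sizes give stable
statistics while keeping a full run in the tens of seconds on one CPU.

## Numerical and degenerate-input choices

* Medians use the standard convention (middle order statistic, or the mean
  of the two middle ones).
* Empty survivor sets at any stage are warnings, not errors, so parameter
  sweeps complete; empty intersections likewise.
* Self-loops in input edge lists are dropped (counted and logged); duplicate
  and reversed-duplicate edges collapse; extra TSV columns (weights) are
  ignored with a warning.
* p-values outside [0, 1], hypergeometric bound violations, non-positive or
  non-finite Ct values, and negative consumptions raise immediately.
* The C-T-P-D `size_score` is degree / max degree — proportionality is the
  contract; absolute pixel sizes are a rendering concern and out of scope.

## Known limitations

* The cascade's outcome depends on the median scope when the candidate hub
  set is small (see above); both scopes are exposed, and reports record
  which was used.
* Enrichment assumes a fixed, complete background; partial annotation
  coverage of the interactome is not modeled.
* The bench module implements the two closed-form formulas only; group-level
  inference (ANOVA, post-hoc tests) is deliberately left to standard
  statistics packages.
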