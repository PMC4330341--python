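# Methods

This note documents the models and procedures implemented in `crossmod`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic benchmarks do and do not demonstrate.

## Node and edge scores

A gene's differential-expression score is the z-value of its mean
treatment expression under a Gaussian fitted to the control samples:
`z = (mean(T) − mean(C)) / SD(C)` with the sample SD (ddof = 1).  At
least two control samples are required unless a global control SD is
supplied; a zero control SD raises unless an explicit `sd_floor` is
configured.  Treatment columns are averaged over the whole window of the
table, so time-course designs should pass the window they want averaged.

Orthogroups collapse the species' genes to single nodes.  Per species,
paralogs aggregate by the signed value of largest magnitude
(`paralog_agg="extreme"`, exact ± ties resolved toward the positive
value); a `"mean"` option exists because extreme-value aggregation can
be distorted by a single outlying paralog.  The combined node score
`Z_i ≥ 0` is the absolute value of the most extreme per-species value;
its sign is kept as metadata.  Edge weights sum integer evidence counts
over species and member-gene pairs; orthogroup-internal interactions are
dropped (the objective is defined over edges between distinct nodes),
and gene symbols match case-insensitively by default because mouse
Title-case and primate/human UPPER-case symbols otherwise fail to join.

## The module objective

```
S_j = (1/σ_Z) Σ_i (Z_i − β_Z μ_Z)/√M + W (Σ_h E_h − μ_E(M))/σ_E(M)
```

* (μ_Z, σ_Z): sample mean/SD of all combined node scores; the √M
  normalisation makes module sizes comparable.
* β_Z (default 1.0): shrinks the per-node centring.  β_Z > 1 leaves
  fewer nodes with positive centred score and therefore yields smaller
  modules; the subtraction is applied **per node** (the alternative —
  subtracting β_Z μ_Z once per module — changes the size scaling and is
  not what the edge term's symmetric construction suggests).
* W (default 0.5): weight of the connectivity term.  W = 0 reduces to
  the classic node-only objective.  The default is a neutral midpoint of
  the grid the `tune` stage searches; analyses with gene-set annotations
  available should prefer the grid recommendation.
* (μ_E(M), σ_E(M)): mean/sample-SD of summed internal edge weight over
  random **connected** size-M node sets, sampled as: uniform seed node
  among nodes whose component can host the size, then repeated uniform
  choice among frontier neighbours.  1000 samples per size by default;
  sizes calibrate lazily up to `max_module_size` (default 150) with a
  per-size RNG stream seeded by `(seed, M)`, so lazy or out-of-order
  calibration is exactly reproducible.  μ_E(1) = σ_E(1) = 0 by
  definition.
* Degenerate σ_E(M) = 0 (regular fixture graphs): the edge term is 0
  when the observed sum equals μ_E(M) and otherwise a signed capped
  value (10⁶) with a warning, avoiding division by zero while keeping
  the ordering of candidates.

## Search

Seeds are nodes ranked by `Z_i` (ties lexicographic); by default every
node above the 95th percentile seeds an expansion (`n_seeds` or an
absolute threshold override this).  Expansion adds, at each step, the
frontier neighbour maximising `S_j`, with equal scores resolved toward
the lexicographically smaller node id.  While the module has fewer than
`min_growth_size = 5` nodes the best neighbour is added even without
improvement — this lets a strong seed climb across a locally flat start —
after which growth stops at the first non-improving step.  The returned
module is the best-scoring prefix of the trajectory, so a forced
non-improving early step is undone if nothing better follows.

Greedy growth has a selection bias: the best of dozens of frontier
candidates scores well above the network mean, so expansions on pure
noise also grow (β_Z is the instrument to suppress this; raising it
shrinks null modules first).  The benchmarks therefore judge signal by
module quality (objective score, mean node activation) against shuffled
controls rather than by the bare existence of modules.

Merging: for every edge internal to at least one seed module, the number
of seed modules containing both endpoints is divided by the larger of
the endpoints' appearance counts; edges with ratio strictly above
`merge_cutoff` (default 0.25; sensible range 0.1–0.4) are kept, final
modules are the connected components of the kept-edge graph, components
with fewer than `min_final_module_size = 4` nodes are dropped, and each
component is re-scored with the objective.  Because modules are induced
subgraphs, counting modules in which an edge is internal equals counting
co-membership of its endpoints; the `merge_count="edge"` switch exists
for searches that track traversed edges explicitly.

## Conservation calls

`Diff = Σ|Z_iA − Z_iB|/√M` and `Active(X) = Σ|Z_iX|/√M` are compared
against `n_random = 10 000` uniform same-size node subsets — connectivity
deliberately **not** required — drawn from the pool of nodes belonging to
any final module.  Percentiles are upper-tail fractions (random ≥
observed, ties counted).  Categories: CM if `diff_pct > 0.95`; for
`diff_pct < 0.05`, OP if `active_pct < 0.05` in both species, SP if in
exactly one; everything else is unclassified.  "High activation"
consistently means a small upper-tail percentile; the SP definition
requires high activation in exactly one species, which makes the three
categories mutually exclusive.  A node missing one species' score
contributes `|Z_present − 0|` to Diff (logged).

Two structural facts about this calibration are worth knowing.  The
pool is made of module members, i.e. mostly activated nodes, so an SP
module's Diff sits mid-range whenever the pool also contains
opposite-regulation mass — SP calls are reliable only when divergent
nodes are rare in the pool, which is the situation in real data where
most modules are conserved or unclassified.  And a CM call needs some
genuinely divergent mass in the pool, otherwise "less divergent than
95% of random modules" is unattainable.  The conservation benchmark
fixture (below) is designed with both constraints in mind.

## Temporal matching

Per-time-point module sets are produced by the same search on
time-point-specific scores.  Every ordered pair of time points (not only
consecutive) is tested; a link requires hypergeometric `P(X ≥ k) < 0.01`
in both argument orientations.  With a fixed universe the two
orientations coincide by symmetry; a stricter optional mode additionally
requires mutual best match.  The universe defaults to the number of
orthogroup nodes in the joint network.  No multiple-testing correction
is applied to match p-values — the 0.01 threshold is used raw, which is
the convention this analysis follows.  Fan-in (several early modules
matching one later module) is expected and kept.  For cascade endpoint
layouts, each terminal-module node is assigned the earliest time at
which it belonged to any matched ancestor module.

## Enrichment and parameter selection

Modules expand to the union of member genes over both species (combined
annotation namespaces).  Per module, each gene set gets an upper-tail
hypergeometric p against a configurable universe (default: all genes of
the network's orthogroups), corrected across that module's tests by
Bonferroni (default) or Benjamini–Hochberg; significance at α = 0.05
after correction.  A set is *uniquely* enriched for a module when it is
significant there and in no other module.

The (W, β_Z) grid runs the full search per combination (sharing the
edge background, which depends on neither) and records: (i) % modules
with ≥ 1 uniquely enriched set, (ii) % differentially expressed nodes
among module nodes (DE = combined score scaled by the network maximum
> 0.25), (iii) module count.  The recommendation maximises the
within-grid rank sum of (i) and (ii), breaking ties toward fewer modules
and then deterministically.  How to combine the three criteria is
genuinely open; the rank-sum rule is transparent and scale-free, and the
full grid table is always emitted so users can overrule it.

## Null models

* `shuffle_expression`: per-species scores permuted independently across
  scoring nodes; topology bit-identical; combined scores recomputed.
* `switch_edges`: repeated double-edge swaps (a–b, c–d → a–d, c–b),
  rejecting self-loops and multi-edges, weights travelling with edges;
  10×|E| attempted swaps by default (the standard degree-preserving
  MCMC choice).

## Synthetic benchmarks — what they show

The generator plants connected modules in an Erdős–Rényi background
(mean degree 6, unit weights, per-species scores N(0,1)).  Planted
blocks get a random spanning tree plus internal edges at probability 0.5
carrying weight 3 (emulating interactions supported in both species);
background edges directly bridging two planted blocks are removed, since
adjacent activated blocks would form a single active region and leave
the ground truth ill-defined.  Patterns: conserved (same signed effect
both species), species-specific (effect in one, N(0,1) in the other),
opposite (±effect), all plus N(0, 0.5) noise; `active_fraction < 1`
leaves part of a block at background scores to emulate members recruited
through interactions only.

Benchmark conditions (chosen up front, by the power analysis sketched
below):

* **Recovery**: 200 nodes, three 8-node modules (conserved / species-A /
  opposite) at effect 3.0 — mean best-match Jaccard over 20 generator
  seeds ≥ 0.8.
* **Conservation calls**: 250 nodes, four 12-node modules — three
  conserved at effect 2.5 and one opposite at 3.5 — so the module-member
  pool holds conserved *and* divergent mass and the effect contrast
  separates the opposite module's activation from the pool mean by
  ≈ 4 null-SDs: both CM and OP calls are then identifiable at the
  0.05/0.95 cutoffs with per-module failure probability ≈ 1%.
* **Cascades**: 150 nodes, one persistent 12-node module growing from a
  third of its nodes to all of them over three time points, plus one
  transient module at the middle time point; the persistent module
  should form the unique full-length chain.

Emitted fixture files reproduce the generated network exactly: control
samples have mean 0 and sample SD exactly 1, treatments are constant at
the target z, and joint edge weights are split into per-species evidence
lines that re-sum on assembly.

What passing these benchmarks does **not** show: real interaction
networks are scale-free and far sparser per gene; real expression noise
is heteroskedastic and correlated across genes; real orthogroups have
paralog structure (the generator uses 1:1 groups); and real module
boundaries are not cleanly disjoint.  The benchmarks validate the
machinery — objective, search, calibration, calls, matching — not
biological discovery performance.

## Known limitations

* Conservation analysis is defined for exactly two species; more species
  would need a phylogenetic divergence model.
* The L1 divergence ignores correlated expression changes (a module
  shifted equally in both species scores as conserved even if both
  shifts are artefactual).
* Greedy search is a heuristic; on small exhaustively-enumerable graphs
  it attains the optimum in the bundled cases, but no guarantee exists
  in general (the exhaustive-oracle tests quantify agreement rather than
  assume it).
* Confidence-weighted edges (e.g. log-likelihood scores) are not
  implemented; evidence counts are the only edge weighting.
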