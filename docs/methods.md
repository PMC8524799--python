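# Methods

## Model and procedure

The package anonymizes an attributed, undirected, unweighted social
network. Entities carry `p` numerical and `q` categorical attributes; the
network is a symmetric binary adjacency matrix. A release is a partition
`PS = {s_1..s_m}` of the entities into clusters of at least `k` members,
published as supernodes with generalized attributes (interval hull per
numerical attribute, hierarchy LCA per categorical attribute) and
intra-/inter-cluster edge counts. Two normalized losses in [0, 1] measure
the damage: generalization loss (GLoss) over the attributes and structure
loss (SLoss) over the hidden edges; the combined clustering loss is their
unweighted sum. The greedy algorithm seeds each cluster at the unassigned
node of maximum degree and grows it to size `k` by repeatedly absorbing
the unassigned node of minimal blended cost
`a·(Attr+Cate)/(p+q) + (1−a)·D(v,s)`; leftover nodes (fewer than `k`)
are appended to existing clusters, so every cluster ends with ≥ k members.

### Assumptions

* The graph is simple, undirected and unweighted; directed input is
  rejected at the reader level, self-loops are dropped with a warning,
  duplicate edges collapse.
* Records are complete: missing or non-finite values are rejected at read
  time, with no imputation.
* Every categorical value resolves to a leaf of its attribute's
  generalization hierarchy.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `k` | minimum cluster size (anonymity level) | — (user) | integer ≥ 2; `k = 1` is vacuous and rejected; `k > n` rejected |
| `a` | attribute-vs-structure weight | — (user) | in [0, 1]; `a = 1` clusters purely on attributes, `a = 0` purely on structure |
| sweep grids | benchmark evaluation grid | k ∈ {3, 6, …, 30}, a ∈ {0, 0.2, …, 1} | the grid of the original benchmark study |
| `mean_degree` | synthetic network density | 4.0 | sparse social networks average a handful of contacts per person |
| `model` | synthetic edge model | `er` | `er`: G(n, p) with p = mean_degree/(n−1); `ring`: ring lattice with seeded rewiring |
| `rewire_prob` | ring-model rewiring probability | 0.1 | 0 keeps the pure lattice |

## Design choices where the design was open

* **Disconnected pairs.** The node distance `L/(L+1)` is undefined when no
  path exists; such pairs are assigned its supremum, 1.0 (maximal
  dissimilarity), preserving the [0, 1] range. The synthetic networks are
  not guaranteed connected, so this case is exercised routinely.
* **Weight semantics.** The two loss scales are blended as a convex
  combination (`β = 1 − α`), the minimal reading under which a single
  weight `a ∈ [0, 1]` controls the trade-off. The candidate cost uses the
  *would-be generalization factors of the grown cluster*, normalized to
  [0, 1] by `p + q`, so both cost terms share a scale.
* **Total loss.** Reported as the unweighted sum GLoss + SLoss. This is
  the unique combination consistent with the bundled benchmark grids,
  whose best generalization cell (0.118513) and best structure cell
  (0.184306) at (k=3, a=1) sum exactly to the recorded minimum clustering
  loss 0.302819. The weight `a` steers the clustering, not the report.
* **Inter-cluster loss bound.** The published bound `Σ |s_i||s_j|/4`
  disagrees with the interSL formula it bounds: maximizing
  `2E(1 − E/(|s_i||s_j|))` over the edge count gives `|s_i||s_j|/2` at
  `E = |s_i||s_j|/2`. `structural_loss_bounds` returns the published
  values verbatim for fidelity; `derived_inter_bound` exposes the true
  maximum, which is what makes SLoss ≤ 1 provable
  (`Σ_j C(|s_j|,2)/2 + Σ_{i<j} |s_i||s_j|/2 = n(n−1)/4` exactly). The
  intra bound `Σ |s_j|(|s_j|−1)/4` is the *real-valued* maximum of the
  summed intraSL; for clusters where `C(|s_j|,2)` is odd no integer edge
  count attains it, so tests check attainment in the real-valued sense and
  domination over all integer counts.
* **Tie-breaking.** Seed selection, candidate selection and leftover
  placement all break ties on the smallest input-file index (node order =
  node-CSV row order), making the algorithm fully deterministic without
  randomness. No swap/re-optimization phase follows the greedy pass.
* **Degree-based seeding vs. `a = 1`.** Because seeds are always chosen
  by maximum degree, even a pure-attribute clustering (`a = 1`) depends on
  the edge set through the seed order. Costs at `a = 1` are provably
  edge-independent, and partitions coincide across graphs with identical
  degree rankings; full edge-set invariance at `a = 1` does not hold and
  is not claimed.
* **Default hierarchies.** Gender (M/F), Smoke (Y/N) and Marriage
  (Single/Marriage/Divorce) are flat height-1 trees; zip codes use a
  3-level tree (full code → 3-digit prefix → root, height 2), built from
  the observed codes. All hierarchies are overridable through the JSON
  hierarchy file, and the benchmark trees are a reconstruction — the
  original study's exact trees (especially the zip levels) are not
  recoverable, which limits comparability of absolute GLoss values.
* **Zero global range.** A numerical attribute that is constant across
  the dataset contributes 0 to Attr (any cluster is already fully
  specific on it), avoiding a 0/0.
* **Masked-graph formats.** GraphML (via networkx) and an equivalent JSON
  document; intervals serialize as `lo..hi` strings in GraphML. Superedges
  with zero cross count are omitted. Both formats round-trip exactly.

## Synthetic data: what it emulates and what it does not

The 60-patient benchmark table ships verbatim, but its social network was
never published; `synth_edges` stands in with a seeded Erdős–Rényi graph
(default mean degree 4) or a rewired ring lattice. These reproduce a
realistic *sparsity* but none of the community structure, degree skew or
attribute-edge correlation a real patient network would show. Passing
tests therefore demonstrate the pipeline's invariants (k-anonymity, edge
conservation, loss ranges, determinism, oracle agreement) on such
networks — they do not certify that recomputed loss *values* match the
recorded benchmark grids, which additionally depend on the unpublished
edge list, the original hierarchy trees, and unspecified tie-breaking.
`regression_report` makes that comparison explicit: it recomputes the
grid cells the benchmark study singles out (best generalization loss
0.116333 at k=21, a=1; best structure loss 0.150157 at k=3) on either a
user-supplied real edge list or the synthetic stand-in, and reports the
deviation with a per-cluster breakdown (sizes, internal edge counts,
intraSL terms) so discrepancies can be traced.

One transcription ambiguity in the benchmark table (the zip code of the
three matching records 1/23/46 renders as both 63613 and 33613 in
different printings) is resolved to 33613 for all three.

## Numerical choices

* Shortest paths: breadth-first search (networkx), cached as an all-pairs
  hop matrix per graph object; `inf` marks disconnected pairs.
* All losses are plain double-precision arithmetic; the independent naive
  oracle (Floyd–Warshall plus nested-loop formulas) agrees to 1e−12 in
  tests.
* The brute-force optimal-partition oracle enumerates all set partitions
  with blocks ≥ k and is capped at n ≤ 10 (Bell-number growth); ties on
  total loss break by lexicographic canonical encoding.
* Problem sizes in the test suite: random property instances use n = 7–9
  with 100–200 seeds; oracle-equivalence runs 20 instances at n = 8,
  k = 2; the benchmark sweep runs the full 10 × 6 grid on n = 60 once per
  session and is shared across tests.

## Known limitations

* Greedy clustering carries no optimality guarantee; on small instances it
  is only validated to never beat the exhaustive optimum.
* No l-diversity / t-closeness style protection of the sensitive
  attribute: a cluster may be diagnosis-homogeneous.
* Leftover absorption can make one cluster substantially larger than `k`
  (up to `k + (k−1)` via leftovers, or n when `k > n/2`).
* The linkage auditor models exact joins (optionally after generalization)
  only; probabilistic record linkage is out of scope.
* Monotonicity of generalized linkage match sets is guaranteed only for
  nested coarsenings (hierarchy levels; numeric bin widths that divide
  each other).
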