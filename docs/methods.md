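# Methods

## Model and procedure

`endoprox` measures whether a drug's protein targets are closer, in network
terms, to a disease endophenotype module than chance predicts, and screens
a catalog of such modules for significant proximity.

**Distance.** All distances are unweighted hop counts on an undirected,
simple protein–protein interaction graph. For module *A* and target set
*B*, the closest distance is the symmetrised average of each node's minimum
hop distance to the other set:

    d_AB = ( Σ_{a∈A} min_{b∈B} d(a,b) + Σ_{b∈B} min_{a∈A} d(a,b) ) / (|A|+|B|)

d_AB = 0 exactly when every member of each set has a zero-distance
counterpart in the other, i.e. when the restricted sets are equal; mere
overlap zeroes only the overlapping terms. Genes shared between targets and
a module are kept in both sets (their terms contribute zeros); no overlap
removal is applied.

**Null model and significance.** The null resamples, for each replicate, a
degree-matched stand-in for each set: every node is replaced by a node
drawn uniformly from the same *degree bin*, without replacement within the
set. Default mode resamples both sets; a `B-only` mode (targets only,
module fixed) is provided because either convention appears in the
proximity literature. The z-score standardises the observed distance by the
replicate mean and the replicate sample SD (ddof = 1). The empirical
p-value is one-sided toward small distances with the add-one rule
p = (r+1)/(n+1), r = #{null ≤ observed}; it can never be 0. A degenerate
null (SD = 0, possible on tiny graphs with singleton bins) yields a flagged
NaN z rather than ±∞; the empirical p is still reported. A normal-theory
lower-tail p (Φ(z)) is reported alongside for reference. A module passes
the screen iff z < z_threshold AND p < p_threshold.

**Assumptions.** The interactome is treated as a single undirected simple
graph; edge direction, sign and confidence are out of scope. All proximity
computation is restricted to the largest connected component — hop
distances are otherwise infinite — and set members outside the component
are dropped with a logged coverage report. Degree-preserving resampling
assumes the degree bins are fine enough that "similar degree" is
meaningful, and coarse enough that each bin offers real sampling diversity.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `n_permutations` | 10,000 | null replicates per module; the add-one p floor is 1/10,001 |
| `z_threshold` | −1.8 | proximity screening cut on the z-score |
| `p_threshold` | 0.05 | screening cut on the empirical p |
| `min_bin_size` | 100 | minimum nodes per degree bin; common practice for ~10⁴-node interactomes, keeps hub bins from becoming near-deterministic |
| null mode | `both` | resample both sets per replicate; `B-only` keeps the module fixed |

Degree bins are built greedily: nodes sorted by degree, equal degrees never
split, classes accumulated until the bin reaches `min_bin_size`, trailing
remainder merged downward. On the default synthetic graph this yields ~8
bins, so the null is far from trivial.

**Seeding.** A single master seed governs a screen. Each module's
permutation stream derives from `SeedSequence([master, blake2b(name)])`, so
results are invariant to catalog order and to adding/removing other
modules — a property a counter-based child-seed scheme would not have.
Screens with the same inputs and seed are byte-identical.

## Numerical and implementation choices

The permutation loop runs against a precomputed all-pairs hop-distance
matrix (`scipy.sparse.csgraph`, BFS per source), with replicates drawn and
evaluated in vectorised blocks of 2,048; memory is 8 bytes per node pair
(~32 MB at 2,000 nodes, ~2.5 GB at 17,700 — feasible on a workstation, and
the matrix is computed once per graph regardless of catalog size).
Within-bin sampling without replacement uses the k-smallest-of-iid-uniforms
construction (`argpartition` of a random matrix), which is an exact uniform
k-subset draw. The public `closest_distance` deliberately takes an
independent route — two multi-source BFS passes on the adjacency structure —
so the matrix path and the BFS path cross-validate each other in the test
suite, alongside a brute-force Floyd–Warshall oracle. Screen TSVs are
written with fixed `%.6g` float formatting to make byte-level determinism
checks meaningful. Ranking ties (equal z, equal degree) break
lexicographically; NA rows (zero-coverage modules) sort last.

## Synthetic data: what it emulates, and what it does not

The generator emulates three statistical features of real inputs: a
heavy-tailed-degree background graph (Barabási–Albert preferential
attachment, `m = 3`, so mean degree ≈ 6, comparable to curated
interactomes' sparse connectivity), module sizes spanning 10–120 genes, and
a controllable proximity relationship: *planted* modules are sampled from
the union of ≤ r-hop neighbourhoods of the targets (default r = 1), decoys
from nodes ≥ 3 hops from every target when that pool suffices, else
uniformly. Defaults — 2,000 nodes, 46 targets, 25 modules, 5 planted —
mirror the motivating use case's target-set and catalog sizes while keeping
a full screen desk-fast; the graph is deliberately smaller than a real
~17,700-protein interactome. Category labels cycle through the six named
endophenotype classifications.

What it does **not** emulate: literature-curation noise and ascertainment
bias in target lists, correlated module overlap (real pathological
processes share many genes), community structure and clustering of real
interactomes (BA graphs are locally tree-like), and identifier-namespace
mismatches. Passing tests therefore demonstrate that the statistic,
null and screen behave correctly — not that any particular biological
screen's conclusions are right; on real data, coverage reports and the
choice of identifier mapping matter as much as the statistic.

## Validation problem sizes

The acceptance checks run at: 200 random graphs (≤ 50 nodes) for oracle
equivalence; 9 singleton-pair exhaustive-null comparisons at 10,000
permutations; 1,500 random module/target pairs at 1,000 permutations each
for z calibration (the larger replicate count keeps Monte-Carlo error on
the mean well inside the ±0.1 band); 100 independent scenarios at 1,000
permutations per module for planted recovery — 1,000 permutations gives a
p floor of ~0.001, ample for a 0.05 cut, while the package default of
10,000 remains what a real screen uses and what the full-depth
demonstration screen in `scripts/acceptance.py` uses.

## Known limitations

* The whole-matrix distance cache trades memory for speed; graphs much
  beyond ~30k nodes need the BFS route or a chunked cache.
* Empirical p-values are not corrected for multiple testing across
  modules; the screen reports raw per-module significance by design.
* The degree-binning scheme (greedy contiguous, min 100) is one reasonable
  realisation of "degree-preserving"; published screens rarely state
  theirs, so exact z reproduction across tools should not be expected
  beyond permutation error.
* On graphs with highly degenerate degree structure (regular graphs), the
  null collapses toward uniform resampling; the degenerate-SD flag guards
  the pathological extreme.
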