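# Methods

## Problem setting

A protein–protein interaction (PPI) network is an undirected graph over
protein identifiers (systematic yeast ORF names by convention), optionally
with a reliability weight per edge. Protein complexes appear as dense,
possibly overlapping subgraphs. Experimental networks are incomplete;
text-mining systems supply additional candidate interactions, each carrying a
real-valued confidence score whose scale is the extractor's own (the useful
thresholds in practice run from 0 down to about −0.9, so scores are allowed
to be any finite real). `litppi` measures the value of such records by
integrating them into a network at a confidence cutoff, re-running complex
detection, and scoring the result against reference catalogs across a grid
of cutoffs.

## Network model and hygiene

Edge lists are tab-separated, undirected, with pairs canonicalized
lexicographically; duplicate pairs resolve first-wins with a logged warning.
Self-interactions and isolated proteins carry no information for complex
detection and are removed by an explicit hygiene filter (reading and
filtering are separate steps so that raw files round-trip). Density of a
member set of size n is total internal edge weight over n(n−1)/2; with
weights above 1 the value can exceed 1 and is deliberately not clamped.
Transitivity is the global clustering coefficient of the unweighted topology
(3 × triangles / connected triples; 0 with a warning when no triple exists).

## Literature integration

The pipeline order is: threshold gate (score ≥ t, boundary inclusive) → drop
records with an endpoint the network does not contain (the protein universe
is never extended) → drop records whose pair already exists (native edges
and weights are never overwritten) → attach weights → add edges. On
unweighted networks the scores are discarded. On weighted networks the
surviving scores are mapped onto the network's native weight scale;
"proportional adjustment" is implemented as the affine min–max map from the
records' score range onto the network's observed weight range, because it
preserves ranking and produces weights commensurable with native edges.
Alternatives (`mean`, `none`) are exposed as a strategy knob. The map is
computed on the records that survive the threshold and endpoint/duplicate
filters — rescaling before thresholding would let discarded records distort
the anchor points. When all surviving scores coincide the records receive the
network's mean edge weight.

Each threshold in a sweep restarts from the original network, so
integrated-edge counts are per-threshold totals, not increments, and a
stricter threshold's edge set is always nested inside a looser one's.

## Complex detection

Detection follows the cohesiveness-growth scheme for overlapping complexes:

1. **Growth.** Seeds are proteins in decreasing degree order (ties on the
   smaller identifier), skipping proteins already inside a previously grown
   group. From each seed, steepest-ascent local search on
   f(V) = w_in / (w_in + w_bound + p·|V|) applies the single best addition
   of an external neighbor or removal of a non-seed member that strictly
   increases f, stopping at a local optimum. Ties between equally good moves
   break on the lexicographically smallest protein, additions considered
   before removals, so growth is fully deterministic. A guard of 10·|V|
   moves bounds the search; steepest ascent on a bounded score terminates
   long before in practice.
2. **Merging.** While any two groups have overlap score
   ω(A,B) = |A∩B|²/(|A||B|) at or above the merge threshold (default 0.8),
   the highest-ω pair is replaced by its union (ties on the smallest combined
   member tuple).
3. **Filtering.** Groups with fewer than 3 members or density below the
   density threshold are discarded.

The penalty default p = 2 models unobserved interactions. The density
threshold resolves automatically when requested: 0.5 on weighted networks;
on unweighted networks 0.6 when transitivity < 0.3 (star-heavy, sparse
topology where low-density candidates should be discarded) and 0.5
otherwise. The 0.3 cutoff is this package's choice, exposed as a parameter:
only the two outcomes, not the switching rule, are fixed by the behavior
being emulated. No numeric parity with any published clustering binary is
claimed — seeding, tie-breaks and the merge schedule are chosen for
determinism. Other detectors can be registered by name (`cmc`, `coach`,
`rrw` slots exist and raise until an implementation is registered).

## Evaluation

All measures derive from the reference-by-prediction confusion matrix
T_ij = |R_i ∩ P_j| and the overlap score ω. Sn = Σ_i max_j T_ij / Σ_i N_i,
PPV = Σ_j max_i T_ij / Σ_j T_.j, Acc = √(Sn·PPV) (PPV defined as 0 with a
warning when every prediction is disjoint from every reference). The matched
fraction counts predictions with ω ≥ 0.25 (inclusive) against some
reference — 0.25 being the overlap of two equally large sets sharing half
their members. MMR is the total ω-weight of a maximum-weight one-to-one
matching between references and predictions (solved as a rectangular
assignment problem) divided by the number of references. A row-maximum
variant without the one-to-one constraint is exposed as `mmr_rowmax` for
diagnostics; it upper-bounds MMR and coincides with it exactly when the
per-reference best predictions are all distinct. Predictions smaller than 2
proteins are scored as-is; size gating belongs to detection, not scoring.

## Gold standards

MIPS-style catalogs: categories with 3–100 members (inclusive) are complexes;
category 550 and its dotted descendants (unconfirmed, computationally
predicted complexes) are excluded by a component-wise prefix test, so
category "5500" is *not* excluded. GO-derived standards: one complex per
descendant term of the protein-complex term GO:0043234 (root excluded),
membership from annotations after dropping NOT / colocalizes_with qualifiers
and protein–term pairs supported only by IEA evidence (IEA plus any other
code survives). No minimum-size gate is applied on the GO side — GO-derived
catalogs legitimately contain singleton complexes, and the same protein may
appear in many complexes. Terms annotate per-term by default; folding
descendants' proteins into a term is available behind a `closure` flag.
Ontology input is either a minimal OBO parse (id / is_a / part_of only —
full OBO semantics are out of proportion to one reachability query) or a
two-column child–parent table.

## Synthetic benchmarks

The generator plants `n_complexes` complexes (sizes uniform in `size_range`,
default 12 complexes of 4–9 proteins), wires within-complex pairs with
probability `p_in` (default 1.0) and all remaining pairs with `p_noise`
(default 0.02), and by default emits weighted networks with edge weight
clip01(base + N(0, 0.1)), base 0.8 for true edges and 0.3 for noise —
mimicking reliability-scored TAP data, where weights encode confidence. A
quarter of complexes (default) swap one or two members with an earlier
complex to produce overlap. A fifth of the true edges (default) are withheld
from the network and emitted as literature records under the proteins'
common names (exercising alias normalization), scored N(0.8, 0.1); 300
spurious protein pairs are emitted at N(−0.8, 0.1), making the stream
dominated by low-confidence records the way real extraction output is. All
randomness flows from one integer seed through a single generator; fixed
seed, identical output.

What the generator does not emulate: the heavy-tailed degree distribution of
compendium networks (a pure planted-complex topology), extraction errors
beyond the two-Gaussian score model, and biological name ambiguity (aliases
are bijective). Passing tests therefore demonstrate that the machinery is
correct and that the threshold logic behaves as designed under calibrated
scores — not that any particular real network will show the same gains.

## Test and benchmark sizes

Unit and property tests run on hand-sized fixtures (≤ 12 proteins) with
exhaustive or hand-computed oracles: the matching-based MMR is checked
against brute-force enumeration of all one-to-one mappings on 200 random
fixtures with up to 6 complexes a side. Recovery tests use 6 planted
complexes of 4–8 proteins at p_in = 1 and p_noise = 0.05 over 10 seeds,
asserting every planted complex is found with ω ≥ 0.9; recovery is measured
on the generator's default weighted networks, where noise edges carry low
weights — on unweighted planted networks at the same noise level, noise
edges weigh as much as complex edges and near-exact recovery by greedy
cohesiveness growth is not an appropriate expectation. The sweep behavior
(positive average MMR gain at threshold −0.6, declining by −0.9) is asserted
over 5 seeded default benchmarks. The full suite runs in a few seconds on
one CPU.

## Numerical choices and degenerate inputs

Cohesiveness of a group with zero denominator (isolated single protein,
penalty 0) is 0. Growth accepts a move only if it improves the score by more
than 1e−12, preventing cycling on floating-point ties. Density requires at
least 2 members; Sn and MMR require a non-empty reference set; an empty
prediction set scores 0 everywhere. Mean gold-standard complex size is
reported to one decimal. Sweep deltas are relative percent changes,
100·(v − origin)/origin; with a zero baseline the delta is reported as 0
when the value is also 0 and infinity otherwise.

## Known limitations

- The detector is a faithful *scheme* implementation, not a port: numeric
  agreement with any published clustering tool on real data is out of scope.
- Real catalog snapshots (MIPS, SGD) and real PPI datasets are not bundled;
  all quantitative claims in the test suite concern synthetic benchmarks.
- The row-max MMR variant is diagnostic only; all reported MMR values use
  the one-to-one matching.
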