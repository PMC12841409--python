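# Methods

## Model

A chromosome variant is a signed permutation of `n` syntenic blocks: an
ordered sequence over labels `1..n`, each appearing once, where a negative
sign marks a block whose internal gene order is flipped relative to the
ancestral reference. Positions are 1-based and inclusive throughout the
permutation layer; conversions happen only at I/O boundaries. The framing
convention (a virtual block `0` at the distal/telomeric end and `n + 1` at
the centromeric end) fixes the chromosome's orientation, so arrangements
are compared as linear, oriented sequences — reflections are *not*
identified. Only inversions within the one chromosome are modelled; no
translocations, fusions or fissions.

All comparisons are reduced to sorting a *relative* permutation to the
identity: the source arrangement is composed with the inverse of the
target, which preserves reversal distance and breakpoint structure.

## Exact solver

`reversal_distance` runs iterative-deepening depth-first search over
reversal sequences, pruned with the larger of two admissible lower bounds:

- `⌈b/2⌉`, where `b` is the framed breakpoint count (one reversal repairs
  at most two framed adjacencies);
- `n + 1 − c`, where `c` is the number of cycles in the breakpoint graph
  (one reversal increases the cycle count by at most one).

Both bounds never overestimate, so the first threshold at which the search
succeeds is the exact distance. The cycle bound is what makes random
8-block instances (typical distance 7–9) immediate; with the breakpoint
bound alone the search tree explodes when the distance is close to `b`.
Search was chosen over a closed-form polynomial distance because the block
counts this tool targets are tiny (default cap `max_n = 12` blocks, refused
loudly above that) and a search is auditable; the package instead carries
an independent exhaustive cross-check, `bfs_distance_table`, a vectorized
breadth-first search over the entire reversal graph (`n! · 2^n` states;
~10.3 million at `n = 8`), used by the test suite to verify the solver
state-by-state at `n ≤ 5` and on 1,000 random 8-block pairs.

`minimal_scenarios` enumerates *every* reversal sequence of exactly minimal
length by bounded DFS with the same pruning. A sequence of minimal length
can never revisit an arrangement (a revisit would imply a shorter
sequence), so each scenario is generated exactly once. Scenarios are
emitted in the canonical order induced by trying reversals in lexicographic
`(start, end)` order at every step; the enumeration truncates at
`max_scenarios` (default 10,000) with an explicit flag rather than
silently. When more than one minimal scenario exists — as for the two
nesting orders of the worked example's fixed inversions — the count is
always reported; the tool never presents one minimal scenario as unique.

There is no randomness anywhere in the distance layer; byte-identical
output across runs is a test invariant.

## Greedy heuristic

`greedy_scenario` is the simplest classical guaranteed-terminating greedy:
at each step apply the reversal that maximally reduces the framed
breakpoint count, breaking ties by shorter span and then leftmost start.
If no reversal reduces the count — possible only while every block is
positively oriented relative to the target — the leftmost maximal strip
whose flip does not increase the count is reversed. The flip creates a
negatively oriented strip, after which a breakpoint-removing reversal is
guaranteed to exist, so the procedure terminates; its length is bounded
below by the exact distance, and the test suite measures (rather than
assumes) how often it attains the optimum (~75–80% on uniform random pairs
with `n ≤ 7`, and it does attain it on the worked example). The heuristic
exists as a transparent, polynomial-time counterpart to the exact solver,
not as a replacement for it.

## Synteny blocks from breakpoint regions

A breakpoint region (BR) is the physical interval between two flanking
gene markers known to bracket an inversion breakpoint. Conventions:

- Marker coordinates are 1-based inclusive spans on the reference
  assembly; strand is carried but does not affect gap computation.
- The **inner gap** of a BR is `start(downstream gene) − end(upstream
  gene)`, upstream/downstream decided by coordinate, not by the
  distal/proximal roles; overlapping spans yield a negative gap, reported
  unclamped. This gap is the mapping resolution achievable from the
  *gene-level* spans; published resolutions computed from exon-level probe
  endpoints will generally differ, so the package documents its convention
  and does not claim to reproduce exon-level figures.
- A BR whose flanks lie further apart than `derived_junction_threshold`
  (default 1 Mbp) on the reference axis cannot be an intact ancestral
  adjacency; it realizes a *derived* junction created by an earlier
  inversion. Such regions are refused by `gap_bp` and contribute no
  ancestral boundary.
- Each remaining BR contributes one boundary on the ancestral axis: an
  explicit abstract edge (`k` = "between ancestral blocks k and k+1") when
  coordinates for the boundary are unavailable, else the midpoint of its
  inner gap. Colocated BRs (two regions occupying one physical junction)
  contribute a single shared boundary; the partition is invariant to input
  order and to which member of the pair carries the colocation arrow.

Block counts follow: `blocks = distinct boundaries + 1`, numbered
distal→centromeric. `disrupted_blocks` counts coarse blocks with at least
one new boundary strictly interior — a colocated breakpoint reuses an
existing junction and disrupts nothing, which is exactly the asymmetry the
worked example shows (X2 disrupts 1 of 5 coarse blocks, X0 disrupts 2).

In the packaged fixture the four fixed-inversion BRs are pinned to
abstract edges `1|2`, `2|3`, `4|5`, `6|7`: these are forced by the X1
arrangement arising from the two nested fixed inversions, but the
assignment of the names BRI–BRIII to specific junctions is conventional
(only the proximal outer boundary, BRIV, is constrained by the
colocalization data), so those three carry no coordinates.

## Mapping simulator

`simulate_mapping` idealizes iterative FISH mapping of one inversion
breakpoint as noiseless bisection over a marker catalog. Eligibility
follows the bench rules: a probe needs a unique sequence and either one
exon ≥ 500 bp or at least two exons of 100–200 bp (amplified with the
intervening intron). The policy queries the unqueried eligible marker
nearest the current bracket midpoint; the inside/outside verdict reveals
the marker's side of the breakpoint and the bracket shrinks to it; the run
stops when no unqueried eligible marker remains strictly inside. Provable
invariants, all tested: the bracket always contains the true breakpoint,
its width is non-increasing, and the final bracket is exactly the gap
between the nearest eligible markers flanking the breakpoint — resolution
is set by local marker density and nothing else. The bench procedure's
actual marker-choice rule is not published; nearest-midpoint bisection is
this package's explicit idealization, and with strongly clustered markers
it can take more (never incorrect) iterations than an index-median rule
would. The two breakpoints of an inversion are two independent runs.

Randomness is confined to catalog generation (`random_catalog`: uniform
distinct marker positions, i.i.d. eligibility) and to the optional
probe-failure hook (default off; a failed probe is uninformative and the
bracket does not shrink). The policy itself is deterministic given a
catalog, and every random entry point takes an explicit seed or generator.

What the synthetic catalogs do *not* emulate: clustered real gene density,
repeat-rich deserts, hybridization noise, or probes mapping to the wrong
chromosome. Passing simulator tests therefore validate the bracketing
logic and the resolution law, not FISH chemistry.

## Problem sizes and numerical choices

The worked example has `n = 8` blocks; the exact solver is exercised
exhaustively on all signed permutations with `n ≤ 5` and against the full
BFS table on 1,000 random 8-block pairs; the greedy heuristic on 500
random pairs with `n ≤ 7`; the simulator on ~1,000 random catalogs of up
to 120 markers. All ties anywhere (reversal choice, marker choice) are
broken deterministically (lexicographic / distal-first). Degenerate inputs
are first-class: identity-to-identity gives one empty scenario, an empty
BR set gives one block, and zero-length reversals between coincident
junctions are rejected rather than silently ignored.

## Limitations

Single chromosome only; unweighted reversals (no length priors or
probabilistic scenario ranking); block physical lengths in Mbp are out of
scope (they require breakpoint coordinates for the fixed inversions that
the fixture deliberately keeps abstract); exon-level probe endpoints, and
hence published Kbp resolutions derived from them, are not modelled.
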