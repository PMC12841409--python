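# revscen

Reconstruction of single-chromosome inversion (reversal) scenarios between
signed block arrangements, with the supporting machinery a cytogenetics
study needs around it: a synteny-block builder that turns physically mapped
breakpoint regions into block partitions, and an idealized simulator of
iterative FISH-based breakpoint mapping.

## The problem

Closely related dipteran species often differ by paracentric inversions:
segments of a chromosome flipped end-to-end. When the breakpoints of fixed
and polymorphic inversions have been physically mapped against a reference
assembly, each chromosome variant can be written as a **signed
permutation** of syntenic blocks — the order of the blocks along the
chromosome, with a minus sign when a block's internal gene order is flipped
relative to the reference. Asking which variant is ancestral then becomes a
combinatorial question: how many inversions separate each variant from the
outgroup's gene order?

For signed permutations π (relative to a target order) the classical
quantities are:

- **d(π)** — the *reversal distance*: the minimum number of segment
  reversals sorting π to the identity;
- **b(π)** — the number of *breakpoints*: framed adjacent pairs `(a, b)`
  with `b − a ≠ 1` after adding `0` on the left and `n + 1` on the right;
- **c(π)** — the number of cycles in the breakpoint graph.

These satisfy `⌈b(π)/2⌉ ≤ d(π) ≤ b(π)` and `d(π) ≥ n + 1 − c(π)`. revscen
computes d(π) exactly by iterative-deepening search pruned with both lower
bounds, enumerates **all** minimal scenarios in a canonical order, and also
provides a transparent greedy heuristic (maximal breakpoint reduction with
a strip-flip fallback) whose results can be compared against the exact
solver.

The packaged worked example is the X chromosome of the malaria-mosquito
cryptic pair *Anopheles messeae* / *An. daciae*, with *An. atroparvus* as
the outgroup: eight syntenic blocks, the shared X1 arrangement
`1 -6 -5 3 4 -2 7 8`, and the species-specific X2 and X0 arrangements
derived from their mapped breakpoint junctions.

## Worked example

```
$ revscen report --fixture anopheles_x
fixture: anopheles_x
reversal distances:
  ancestral->X1: 2
  X1->X2: 1
  ancestral->X2: 3
  X1->X0: 1
  ancestral->X0: 3
minimal scenarios ancestral->X1: 2 (multiple equally short scenarios)
  1 2 3 4 5 6 7 8 → 1 -6 -5 -4 -3 -2 7 8 → 1 -6 -5 3 4 -2 7 8
  1 2 3 4 5 6 7 8 → 1 2 -4 -3 5 6 7 8 → 1 -6 -5 3 4 -2 7 8
syntenic blocks: 5 (fixed BRs only), 8 (all BRs)
inversion X2 on X1: reversal 3..6, involves 4 blocks [2, 3, 4, 5], disrupts 1 of 5 coarse blocks
inversion X0 on X1: reversal 5..7, involves 3 blocks [2, 4, 7], disrupts 2 of 5 coarse blocks
breakpoint-region gaps (flank-to-flank, bp):
  X2 distal: 14950
  X2 proximal: derived junction, gap suppressed
  X0 distal: 167828
  X0 proximal: 4111
```

Reading the numbers: the shared X1 arrangement is exactly two nested
inversions away from the ancestral (outgroup) gene order — and both
equally short nesting orders are reported, since the data cannot
distinguish them — while the species-specific X2 and X0 arrangements are
each one further inversion beyond X1. That makes X1 the most parsimonious
common ancestor of both species' X variants. The proximal X2 breakpoint
colocalizes with an older fixed-inversion junction, so the X2 polymorphism
disrupts only one of the five coarse syntenic blocks, whereas X0 disrupts
two. The gap lines give the mapping resolution achievable from the
flanking-gene coordinates under the inner-gap convention (see
`docs/methods.md`); a region whose flanks are not ancestrally adjacent is
flagged rather than assigned a meaningless 13 Mbp "gap".

Other entry points: `revscen distance A.txt B.txt`,
`revscen scenarios A.txt B.txt --all --format json`,
`revscen blocks markers.tsv --span 0 8 --json`, and
`revscen simulate-mapping --config sim.yaml --json`. The same operations
are available as a library (`import revscen`).

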