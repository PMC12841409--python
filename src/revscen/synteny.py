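"""Synteny-block partitions from physically mapped breakpoint regions.

A breakpoint region (BR) is the physical interval, bracketed by two flanking
gene markers on the reference assembly, that contains one inversion
breakpoint.  Each BR normally contributes one boundary on the ancestral
chromosome; two BRs that colocalize (occupy the same physical junction)
contribute a single boundary between them, and a BR whose two flanks are
ancestrally distant realizes a derived junction — a junction created by an
earlier inversion — and contributes no ancestral boundary at all.  The
boundaries, together with the chromosome ends, cut the ancestral arrangement
into numbered syntenic blocks.

Boundary positions may be abstract edge indices (``k`` meaning "between
ancestral blocks k and k+1") or base-pair coordinates; the partition logic
only needs them to be ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConstraintError, DerivedJunctionError, InputError
from .signed_perm import Arrangement, Reversal

__all__ = [
    "GeneMarker",
    "BreakpointRegion",
    "SyntenyMap",
    "build_partition",
    "gap_bp",
    "is_derived_junction",
    "reversal_from_junctions",
    "ancestral_junction",
    "involved_blocks",
    "disrupted_blocks",
    "DERIVED_JUNCTION_THRESHOLD_BP",
]

#: Flanks further apart than this on the reference axis are taken to realize
#: a derived junction rather than an ancestral adjacency.
DERIVED_JUNCTION_THRESHOLD_BP = 1_000_000


@dataclass(frozen=True)
class GeneMarker:
    """One flanking gene marker: accession, reference span (1-based,
    inclusive, bp), strand, and the exons the probe was designed from."""

    gene_id: str
    start: int
    end: int
    strand: str
    probe_exons: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"marker {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise InputError(
                f"marker {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )


@dataclass(frozen=True)
class BreakpointRegion:
    """A named breakpoint region with its distal/proximal flanking markers.

    ``ancestral_edge`` pins the region to an abstract boundary "between
    ancestral blocks k and k+1" when reference coordinates for the boundary
    are not available (the usual situation for breakpoints of older, fixed
    inversions).  ``colocated_with`` names another region occupying the same
    physical junction; the pair contributes a single boundary.
    ``category`` distinguishes breakpoints of fixed inversions (species
    differences) from polymorphic ones (segregating within a species).
    """

    name: str
    distal_flank: GeneMarker | None = None
    proximal_flank: GeneMarker | None = None
    colocated_with: str | None = None
    ancestral_edge: int | None = None
    category: str = "polymorphic"

    def __post_init__(self) -> None:
        if (
            self.distal_flank is not None
            and self.proximal_flank is not None
            and self.distal_flank.gene_id == self.proximal_flank.gene_id
        ):
            raise InputError(
                f"region {self.name}: flanks must be distinct genes"
            )

    @property
    def flanks(self) -> tuple[GeneMarker, ...]:
        return tuple(
            m for m in (self.distal_flank, self.proximal_flank) if m is not None
        )


def is_derived_junction(
    br: BreakpointRegion,
    threshold_bp: int = DERIVED_JUNCTION_THRESHOLD_BP,
) -> bool:
    """True when the region's flanks are too far apart on the reference axis
    to be ancestrally adjacent, i.e. the region sits on a junction created by
    an earlier inversion."""
    if len(br.flanks) < 2:
        return False
    a, b = br.flanks
    upstream, downstream = (a, b) if a.end <= b.end else (b, a)
    return downstream.start - upstream.end >= threshold_bp


def gap_bp(
    br: BreakpointRegion,
    threshold_bp: int = DERIVED_JUNCTION_THRESHOLD_BP,
) -> int:
    """Inner gap between the two flanking gene spans, in bp.

    Upstream/downstream is decided by coordinate, not by the distal/proximal
    roles: gap = (start of the downstream gene) - (end of the upstream
    gene).  A negative value (overlapping spans) is reported as-is, not
    clamped.  Regions that realize a derived junction are refused — their
    flank distance on the reference axis is not a mapping resolution.
    """
    if len(br.flanks) < 2:
        raise InputError(
            f"region {br.name}: both flank coordinates are required for a gap"
        )
    if is_derived_junction(br, threshold_bp):
        a, b = br.flanks
        raise DerivedJunctionError(
            f"region {br.name}: flanks {a.gene_id} and {b.gene_id} are not "
            "ancestrally adjacent (derived junction); gap suppressed"
        )
    a, b = br.flanks
    upstream, downstream = (a, b) if a.end <= b.end else (b, a)
    return downstream.start - upstream.end


@dataclass(frozen=True)
class SyntenyBlock:
    label: int
    lo: float
    hi: float

    def contains_interior(self, x: float) -> bool:
        return self.lo < x < self.hi


@dataclass(frozen=True)
class SyntenyMap:
    """An ordered set of ancestral boundaries and the blocks they delimit.

    Blocks are numbered 1..k from the distal (telomeric) end to the
    centromeric end.  ``boundary_sources`` records which breakpoint regions
    contributed each boundary (colocated pairs share one entry).
    """

    boundaries: tuple[float, ...]
    blocks: tuple[SyntenyBlock, ...]
    boundary_sources: tuple[tuple[float, tuple[str, ...]], ...] = field(
        default=()
    )

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_containing(self, x: float) -> SyntenyBlock | None:
        for blk in self.blocks:
            if blk.lo <= x < blk.hi or (x == blk.hi == self.blocks[-1].hi):
                return blk
        return None


def _boundary_position(br: BreakpointRegion, threshold_bp: int) -> float | None:
    """The ancestral boundary a region contributes, or None.

    Preference order: an explicit abstract edge, then the midpoint of the
    inner gap between ancestrally adjacent flanks.  Derived-junction regions
    without an explicit edge contribute nothing.
    """
    if br.ancestral_edge is not None:
        return float(br.ancestral_edge)
    if len(br.flanks) == 2 and not is_derived_junction(br, threshold_bp):
        a, b = br.flanks
        upstream, downstream = (a, b) if a.end <= b.end else (b, a)
        return (upstream.end + downstream.start) / 2.0
    return None


def build_partition(
    brs: Iterable[BreakpointRegion],
    span: tuple[float, float] | None = None,
    threshold_bp: int = DERIVED_JUNCTION_THRESHOLD_BP,
) -> SyntenyMap:
    """Partition the ancestral chromosome at the boundaries the given
    breakpoint regions contribute.

    Each region contributes one boundary unless it is the second member of a
    colocated pair (the pair shares one boundary) or it realizes a derived
    junction without an explicit ancestral edge (it contributes none).
    The block count therefore equals distinct boundaries + 1, and the result
    is invariant to input order and to swapping the roles within a colocated
    pair.
    """
    brs = list(brs)
    by_name = {br.name: br for br in brs}
    for br in brs:
        if br.colocated_with is not None and br.colocated_with not in by_name:
            raise ConstraintError(
                f"region {br.name}: colocated_with names unknown region "
                f"{br.colocated_with!r}"
            )

    # resolve colocation into groups sharing one boundary
    group_of: dict[str, str] = {}

    def root(name: str) -> str:
        while group_of.get(name, name) != name:
            name = group_of[name]
        return name

    for br in brs:
        group_of.setdefault(br.name, br.name)
        if br.colocated_with is not None:
            group_of.setdefault(br.colocated_with, br.colocated_with)
            a, b = root(br.name), root(br.colocated_with)
            if a != b:
                group_of[a] = b

    groups: dict[str, list[BreakpointRegion]] = {}
    for br in brs:
        groups.setdefault(root(br.name), []).append(br)

    positions: dict[float, list[str]] = {}
    for members in groups.values():
        candidates = sorted(
            {
                p
                for br in members
                if (p := _boundary_position(br, threshold_bp)) is not None
            }
        )
        if len(candidates) > 1:
            names = ", ".join(br.name for br in members)
            raise ConstraintError(
                f"colocated regions {names} imply conflicting boundaries "
                f"{candidates}"
            )
        if candidates:
            positions.setdefault(candidates[0], []).extend(
                sorted(br.name for br in members)
            )

    bounds = tuple(sorted(positions))
    if span is None:
        if bounds:
            lo, hi = 0.0, float(bounds[-1]) + 1.0
        else:
            lo, hi = 0.0, 1.0
    else:
        lo, hi = float(span[0]), float(span[1])
        for p in bounds:
            if not (lo < p < hi):
                raise InputError(
                    f"boundary {p} falls outside the chromosome span "
                    f"({lo}, {hi})"
                )
    edges = (lo,) + bounds + (hi,)
    blocks = tuple(
        SyntenyBlock(k, a, b)
        for k, (a, b) in enumerate(zip(edges, edges[1:]), start=1)
    )
    sources = tuple((p, tuple(sorted(positions[p]))) for p in bounds)
    return SyntenyMap(bounds, blocks, sources)


# ---------------------------------------------------------------------------
# junctions on derived arrangements


def _adjacency_index(arr: Arrangement, junction) -> int:
    """Index of a junction in ``arr``: 0 is the left chromosome end, k the
    adjacency between positions k and k+1, n the right end.

    A junction given as a signed pair ``(a, b)`` matches either reading
    orientation (``(a, b)`` or ``(-b, -a)``).  The strings ``"start"`` and
    ``"end"`` name the chromosome ends.
    """
    if junction == "start":
        return 0
    if junction == "end":
        return arr.n
    try:
        a, b = (int(junction[0]), int(junction[1]))
    except (TypeError, ValueError, IndexError):
        raise InputError(
            f"junction must be a signed pair or 'start'/'end', got {junction!r}"
        ) from None
    for k in range(1, arr.n):
        pair = (arr.blocks[k - 1], arr.blocks[k])
        if pair == (a, b) or pair == (-b, -a):
            return k
    raise ConstraintError(
        f"adjacency ({a}, {b}) is not present in arrangement "
        f"{arr.name or arr}"
    )


def ancestral_junction(arr: Arrangement, edge: int) -> tuple[int, int]:
    """The signed adjacency of ``arr`` that realizes the ancestral boundary
    between blocks ``edge`` and ``edge + 1``, in the orientation in which it
    appears in ``arr``."""
    if not (1 <= edge < arr.n):
        raise InputError(f"ancestral edge must be in 1..{arr.n - 1}, got {edge}")
    a, b = edge, edge + 1
    for k in range(1, arr.n):
        pair = (arr.blocks[k - 1], arr.blocks[k])
        if pair == (a, b) or pair == (-b, -a):
            return pair
    raise ConstraintError(
        f"ancestral adjacency {a}|{b} is not intact in arrangement "
        f"{arr.name or arr}"
    )


def reversal_from_junctions(
    arr: Arrangement, left_junction, right_junction
) -> Reversal:
    """The reversal spanning exactly the blocks strictly between two
    junctions of ``arr``.

    Junctions are signed adjacency pairs (or ``"start"``/``"end"`` for the
    chromosome ends); the left junction must precede the right one.
    """
    li = _adjacency_index(arr, left_junction)
    ri = _adjacency_index(arr, right_junction)
    if li > ri:
        raise InputError(
            f"left junction (index {li}) must precede right junction "
            f"(index {ri})"
        )
    if li == ri:
        raise InputError(
            "junctions coincide: a zero-length reversal is not a rearrangement"
        )
    return Reversal(li + 1, ri)


def involved_blocks(arr: Arrangement, rev: Reversal) -> set[int]:
    """Absolute labels of the blocks inside the reversed segment."""
    if rev.end > arr.n:
        raise InputError(f"reversal {rev} out of bounds for n={arr.n}")
    return {abs(b) for b in arr.blocks[rev.start - 1 : rev.end]}


def disrupted_blocks(
    coarse: SyntenyMap, new_boundaries: Sequence[float]
) -> int:
    """How many blocks of a coarse partition contain at least one new
    boundary strictly in their interior.

    Used to ask whether the breakpoints of a younger (polymorphic) inversion
    fall inside the blocks delimited by older (fixed) breakpoints, or reuse
    existing junctions (colocated breakpoints contribute no new boundary and
    so disrupt nothing).
    """
    if not coarse.blocks:
        raise InputError("coarse partition has no blocks")
    lo, hi = coarse.blocks[0].lo, coarse.blocks[-1].hi
    for x in new_boundaries:
        if not (lo <= x <= hi):
            raise InputError(
                f"boundary {x} lies outside the chromosome span ({lo}, {hi})"
            )
    return sum(
        1
        for blk in coarse.blocks
        if any(blk.contains_interior(x) for x in new_boundaries)
    )
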