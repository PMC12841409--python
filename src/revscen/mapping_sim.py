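"""Idealized simulator of iterative physical mapping of an inversion
breakpoint.

The bench procedure being emulated: gene exons from a reference assembly are
hybridized to polytene chromosomes one at a time; each probe lands either
inside or outside the rearrangement, which tells the experimenter on which
side of the breakpoint the marker lies, and the next marker is chosen
accordingly.  The simulator idealizes this as noiseless bisection over a
marker catalog: starting from the whole chromosome, it repeatedly queries the
eligible marker nearest the midpoint of the current bracket until no
unqueried eligible marker remains strictly inside.  The final bracket is then
the gap between the nearest eligible markers flanking the true breakpoint —
the achievable resolution is set by local marker density, nothing else.

Probe eligibility follows the bench rules: a probe needs a unique sequence
and either one large exon (>= 500 bp) or at least two short exons of
100-200 bp (amplified together with the intron between them).

Verdicts are noiseless by default; ``failure_rate`` turns a queried marker
into an uninformative probe (skipped, like a probe that fails to hybridize)
with the given probability.  Randomness is confined to catalog generation
and the optional failure hook; the marker-selection policy itself is
deterministic given a catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "Marker",
    "MarkerCatalog",
    "MappingState",
    "probe_eligible",
    "simulate_mapping",
    "random_catalog",
    "MIN_LONG_EXON_BP",
    "SHORT_EXON_RANGE_BP",
]

MIN_LONG_EXON_BP = 500
SHORT_EXON_RANGE_BP = (100, 200)


def probe_eligible(
    exon_lengths: list[int],
    unique: bool,
    min_long_exon: int = MIN_LONG_EXON_BP,
    short_exon_range: tuple[int, int] = SHORT_EXON_RANGE_BP,
) -> bool:
    """Whether a gene can serve as a FISH probe.

    Eligible iff its sequence is unique in the genome AND it has a single
    exon of at least ``min_long_exon`` bp, or at least two exons whose
    lengths fall in ``short_exon_range`` (two short exons plus the intron
    between them make one probe).
    """
    if not exon_lengths:
        raise InputError("exon_lengths must be non-empty")
    if any(x < 0 for x in exon_lengths):
        raise InputError(f"negative exon length in {exon_lengths}")
    if not unique:
        return False
    lo, hi = short_exon_range
    if any(x >= min_long_exon for x in exon_lengths):
        return True
    return sum(1 for x in exon_lengths if lo <= x <= hi) >= 2


@dataclass(frozen=True)
class Marker:
    id: str
    position: int
    probe_ok: bool = True


@dataclass(frozen=True)
class MarkerCatalog:
    """Markers at strictly increasing positions along one chromosome."""

    chromosome_length: int
    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if self.chromosome_length < 1:
            raise InputError("chromosome_length must be positive")
        pos = [m.position for m in self.markers]
        if any(not (1 <= p <= self.chromosome_length) for p in pos):
            raise InputError("marker positions must lie within the chromosome")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InputError("marker positions must be strictly increasing")

    def eligible(self) -> tuple[Marker, ...]:
        return tuple(m for m in self.markers if m.probe_ok)


@dataclass
class MappingState:
    """Bracketing interval known to contain the breakpoint, plus the query
    history as (marker id, verdict) pairs."""

    bracket: tuple[float, float]
    history: list[tuple[str, str]] = field(default_factory=list)
    bracket_history: list[tuple[float, float]] = field(default_factory=list)

    @property
    def width(self) -> float:
        return self.bracket[1] - self.bracket[0]


def simulate_mapping(
    true_breakpoint: int,
    catalog: MarkerCatalog,
    max_iter: int | None = None,
    inversion_right: bool = True,
    failure_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MappingState:
    """Run the iterative-mapping policy against a hidden breakpoint.

    The policy queries, at each iteration, the unqueried eligible marker
    nearest the midpoint of the current bracket (ties toward the distal
    side); the verdict — inside or outside the rearrangement — reveals which
    side of the breakpoint the marker lies on, and the bracket shrinks to
    that marker.  Stops when no unqueried eligible marker lies strictly
    inside the bracket.

    ``inversion_right`` states on which side of this breakpoint the inverted
    segment lies (toward the centromere by default); it only affects the
    verdict labels, not the bracketing.
    """
    eligible = catalog.eligible()
    if any(m.position == true_breakpoint for m in eligible):
        raise InputError(
            "true_breakpoint coincides with an eligible marker; it must lie "
            "strictly between markers or chromosome ends"
        )
    if not (0 < true_breakpoint < catalog.chromosome_length):
        raise InputError("true_breakpoint must lie inside the chromosome")
    if failure_rate and rng is None:
        raise InputError("failure_rate > 0 requires an rng")

    state = MappingState(bracket=(0.0, float(catalog.chromosome_length)))
    state.bracket_history.append(state.bracket)
    queried: set[str] = set()
    iterations = 0
    while True:
        low, high = state.bracket
        candidates = [
            m
            for m in eligible
            if m.id not in queried and low < m.position < high
        ]
        if not candidates:
            break
        if max_iter is not None and iterations >= max_iter:
            raise InputError(
                f"iterative mapping exceeded max_iter={max_iter}; "
                f"history so far: {state.history}"
            )
        mid = (low + high) / 2.0
        marker = min(candidates, key=lambda m: (abs(m.position - mid), m.position))
        queried.add(marker.id)
        iterations += 1
        if failure_rate and rng is not None and rng.random() < failure_rate:
            state.history.append((marker.id, "failed"))
            state.bracket_history.append(state.bracket)
            continue
        beyond = marker.position > true_breakpoint
        inside = beyond == inversion_right
        state.history.append((marker.id, "inside" if inside else "outside"))
        if beyond:
            state.bracket = (low, float(marker.position))
        else:
            state.bracket = (float(marker.position), high)
        state.bracket_history.append(state.bracket)
    return state


def random_catalog(
    rng: np.random.Generator,
    chromosome_length: int,
    n_markers: int,
    eligible_fraction: float = 1.0,
) -> MarkerCatalog:
    """Draw ``n_markers`` distinct marker positions uniformly along the
    chromosome; each is an eligible probe with probability
    ``eligible_fraction``."""
    if n_markers > chromosome_length:
        raise InputError("more markers than base pairs")
    positions = np.sort(
        rng.choice(chromosome_length, size=n_markers, replace=False) + 1
    )
    ok = rng.random(n_markers) < eligible_fraction
    markers = tuple(
        Marker(f"m{k:04d}", int(p), bool(e))
        for k, (p, e) in enumerate(zip(positions, ok))
    )
    return MarkerCatalog(chromosome_length, markers)
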