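"""Signed block arrangements of a single chromosome and reversals on them.

A chromosome is modelled as a signed permutation: an ordered sequence of block
labels ``1..n`` where a negative sign means the block's internal gene order is
flipped relative to the ancestral reference.  Positions are 1-based and
inclusive throughout this layer; the framing convention (virtual block 0 on
the left, ``n + 1`` on the right) fixes the chromosome orientation
telomere -> centromere.

Arrangements are immutable values: every operation returns a new
:class:`Arrangement`, which makes scenario intermediates safe to store.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import FormatError, InputError

__all__ = [
    "Arrangement",
    "Reversal",
    "Scenario",
    "parse_arrangement",
    "parse_arrangements",
    "apply_reversal",
    "breakpoint_count",
    "relative_arrangement",
    "identity",
]


@dataclass(frozen=True)
class Arrangement:
    """An ordered sequence of signed block labels for one chromosome.

    The absolute labels must be exactly ``{1..n}``, each occurring once.
    """

    blocks: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        blocks = tuple(int(b) for b in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if len(blocks) < 1:
            raise InputError("an arrangement needs at least one block")
        labels = sorted(abs(b) for b in blocks)
        if labels != list(range(1, len(blocks) + 1)):
            raise InputError(
                f"absolute labels must be exactly 1..{len(blocks)}, got {labels}"
            )

    @property
    def n(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[int]:
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def __str__(self) -> str:
        return " ".join(str(b) for b in self.blocks)

    def is_identity(self) -> bool:
        return self.blocks == tuple(range(1, self.n + 1))

    def same_labels(self, other: "Arrangement") -> bool:
        return self.n == other.n

    def adjacencies(self) -> list[tuple[int, int]]:
        """All framed adjacent pairs, including (0, first) and (last, n+1)."""
        framed = (0,) + self.blocks + (self.n + 1,)
        return list(zip(framed, framed[1:]))

    def renamed(self, name: str) -> "Arrangement":
        return Arrangement(self.blocks, name)


@dataclass(frozen=True)
class Reversal:
    """One inversion step: flip the segment ``start..end`` (1-based, inclusive)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InputError(
                f"reversal needs 1 <= start <= end, got ({self.start}, {self.end})"
            )

    def span(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"({self.start},{self.end})"


def identity(n: int, name: str = "") -> Arrangement:
    return Arrangement(tuple(range(1, n + 1)), name)


def apply_reversal(arr: Arrangement, rev: Reversal) -> Arrangement:
    """Return a new arrangement with segment ``[start..end]`` order-reversed
    and every sign inside it flipped; blocks outside are unchanged.
    """
    if rev.end > arr.n:
        raise InputError(
            f"reversal {rev} out of bounds for an arrangement of {arr.n} blocks"
        )
    i, j = rev.start - 1, rev.end
    segment = tuple(-b for b in reversed(arr.blocks[i:j]))
    return Arrangement(arr.blocks[:i] + segment + arr.blocks[j:], arr.name)


def relative_arrangement(arr: Arrangement, target: Arrangement) -> Arrangement:
    """Relabel ``arr`` so that ``target`` becomes the identity.

    This is composition with the inverse of ``target`` in the group of signed
    permutations: reversal distance and breakpoint structure are invariant
    under the relabelling, so every comparison below reduces to sorting the
    relative arrangement to the identity.
    """
    if not arr.same_labels(target):
        raise InputError(
            f"arrangements have different sizes ({arr.n} vs {target.n})"
        )
    inv = [0] * (target.n + 1)  # abs label -> signed position in target
    for pos, b in enumerate(target.blocks, start=1):
        inv[abs(b)] = pos if b > 0 else -pos
    relabelled = []
    for b in arr.blocks:
        v = inv[abs(b)]
        relabelled.append(v if b > 0 else -v)
    return Arrangement(tuple(relabelled), arr.name)


def breakpoint_count(arr: Arrangement, target: Arrangement) -> int:
    """Number of framed adjacencies of ``arr`` that are not adjacencies of
    ``target``.

    After relabelling so that the target is the identity, the sequence is
    framed with 0 on the left and ``n + 1`` on the right, and every adjacent
    pair ``(a, b)`` with ``b - a != 1`` counts as one breakpoint.  The result
    lies in ``[0, n + 1]`` and ``ceil(count / 2)`` lower-bounds the reversal
    distance (one reversal repairs at most two framed adjacencies).
    """
    rel = relative_arrangement(arr, target)
    return sum(1 for a, b in rel.adjacencies() if b - a != 1)


_TOKEN_RE = re.compile(r"^[+-]?\d+$")


def _parse_block_line(line: str, name: str) -> Arrangement:
    tokens = line.split()
    if tokens and tokens[-1] == "$":
        tokens = tokens[:-1]
    if not tokens:
        raise FormatError(f"arrangement {name!r}: no blocks found")
    blocks = []
    for tok in tokens:
        # tolerate the unicode minus that figure captions tend to use
        norm = tok.replace("−", "-")
        if not _TOKEN_RE.match(norm):
            raise FormatError(f"arrangement {name!r}: non-integer token {tok!r}")
        v = int(norm)
        if v == 0:
            raise FormatError(f"arrangement {name!r}: zero is not a valid label")
        blocks.append(v)
    seen: dict[int, str] = {}
    for tok, v in zip(tokens, blocks):
        if abs(v) in seen:
            raise FormatError(
                f"arrangement {name!r}: duplicate label in token {tok!r}"
            )
        seen[abs(v)] = tok
    n = len(blocks)
    missing = sorted(set(range(1, n + 1)) - set(seen))
    if missing:
        raise FormatError(
            f"arrangement {name!r}: missing labels {missing} for n={n}"
        )
    return Arrangement(tuple(blocks), name)


def parse_arrangement(text: str, name: str = "") -> Arrangement:
    """Parse one arrangement from GRIMM-like text.

    Accepts an optional ``>name`` header line, one line of whitespace-
    separated signed integers, and an optional trailing ``$`` terminator
    (accepted and ignored).
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty arrangement text")
    if lines[0].startswith(">"):
        name = lines[0][1:].strip() or name
        lines = lines[1:]
    if len(lines) != 1:
        raise FormatError(
            f"expected a single block line, got {len(lines)} lines"
        )
    return _parse_block_line(lines[0], name)


def parse_arrangements(text: str) -> dict[str, Arrangement]:
    """Parse a multi-record GRIMM-like file into {name: Arrangement}."""
    records: dict[str, Arrangement] = {}
    name: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            name = line[1:].strip()
            if not name:
                raise FormatError("record header '>' without a name")
            continue
        key = name if name is not None else str(len(records))
        if key in records:
            raise FormatError(f"duplicate arrangement name {key!r}")
        records[key] = _parse_block_line(line, name or "")
        name = None
    return records


@dataclass(frozen=True)
class Scenario:
    """An ordered list of reversals together with every intermediate state.

    ``intermediates`` has length ``len(steps) + 1``; the first entry is the
    source and the last the target, and applying ``steps[k]`` to
    ``intermediates[k]`` yields ``intermediates[k + 1]``.
    """

    source: Arrangement
    target: Arrangement
    steps: tuple[Reversal, ...]
    intermediates: tuple[Arrangement, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.intermediates:
            inters = [self.source]
            for rev in self.steps:
                inters.append(apply_reversal(inters[-1], rev))
            object.__setattr__(self, "intermediates", tuple(inters))
        if len(self.intermediates) != len(self.steps) + 1:
            raise InputError("intermediates must have length len(steps) + 1")
        if self.intermediates[0].blocks != self.source.blocks:
            raise InputError("first intermediate must equal the source")
        if self.intermediates[-1].blocks != self.target.blocks:
            raise InputError(
                "scenario does not reach its target: "
                f"ends at {self.intermediates[-1]}, wanted {self.target}"
            )
        for k, rev in enumerate(self.steps):
            got = apply_reversal(self.intermediates[k], rev)
            if got.blocks != self.intermediates[k + 1].blocks:
                raise InputError(f"step {k + 1} does not replay: {rev}")

    def __len__(self) -> int:
        return len(self.steps)

    @classmethod
    def from_steps(
        cls, source: Arrangement, steps: Iterable[Reversal], name: str = ""
    ) -> "Scenario":
        steps = tuple(steps)
        inters = [source]
        for rev in steps:
            inters.append(apply_reversal(inters[-1], rev))
        target = inters[-1] if not name else inters[-1].renamed(name)
        return cls(source, target, steps, tuple(inters[:-1]) + (target,))
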