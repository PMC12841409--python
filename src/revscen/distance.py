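"""Exact reversal distance, minimal-scenario enumeration, greedy heuristic.

The exact solver is a search: iterative deepening depth-first search over
reversal sequences, pruned with admissible lower bounds.  Two bounds are
used, and the tighter one wins at every node:

* ``ceil(breakpoints / 2)`` — one reversal repairs at most two framed
  adjacencies;
* ``n + 1 - c`` where ``c`` is the number of cycles in the breakpoint graph
  of the relative signed permutation — one reversal increases the cycle
  count by at most one.

Both bounds never overestimate the true distance, so iterative deepening
returns exact answers; the cycle bound is what keeps the search tractable on
hard instances (for most signed permutations it is already equal to the
distance).  Search is used instead of a closed-form polynomial distance
because the block counts this tool targets are tiny (n <= 12) and a search
tree is auditable step by step; an exhaustive breadth-first-search table
(:func:`bfs_distance_table`) is provided as an independent cross-check.

There is no randomness anywhere in this module; ties are broken by the
canonical lexicographic order on reversal ``(start, end)`` pairs, so every
output is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import CapExceededError, InputError
from .signed_perm import (
    Arrangement,
    Reversal,
    Scenario,
    apply_reversal,
    relative_arrangement,
)

__all__ = [
    "reversal_distance",
    "minimal_scenarios",
    "ScenarioSet",
    "greedy_scenario",
    "render_scenario",
    "cycle_count",
    "lower_bound",
    "bfs_distance_table",
    "rank_arrangement",
    "SearchStats",
]

DEFAULT_MAX_N = 12


# ---------------------------------------------------------------------------
# lower bounds


def _breakpoints_tuple(rel: tuple[int, ...]) -> int:
    n = len(rel)
    framed = (0,) + rel + (n + 1,)
    return sum(1 for a, b in zip(framed, framed[1:]) if b - a != 1)


def cycle_count(rel: tuple[int, ...]) -> int:
    """Number of cycles in the breakpoint graph of a signed permutation.

    Each signed block ``+x`` is expanded into the ordered point pair
    ``(2x - 1, 2x)`` and ``-x`` into ``(2x, 2x - 1)``; the sequence is framed
    with 0 and ``2n + 1``.  Reality edges join consecutive points across
    block boundaries, desire edges join ``2i`` with ``2i + 1``.  Every point
    has degree two, so the union decomposes into cycles.  The identity has
    ``n + 1`` trivial cycles.
    """
    n = len(rel)
    seq = [0]
    for x in rel:
        if x > 0:
            seq.extend((2 * x - 1, 2 * x))
        else:
            seq.extend((-2 * x, -2 * x - 1))
    seq.append(2 * n + 1)
    # partner tables: each point's reality neighbour and desire neighbour
    reality = [0] * (2 * n + 2)
    for k in range(0, len(seq), 2):
        a, b = seq[k], seq[k + 1]
        reality[a] = b
        reality[b] = a
    cycles = 0
    seen = [False] * (2 * n + 2)
    for start in range(2 * n + 2):
        if seen[start]:
            continue
        cycles += 1
        p = start
        while not seen[p]:
            seen[p] = True
            q = reality[p]
            seen[q] = True
            p = q ^ 1  # desire edge: 2i <-> 2i+1
    return cycles


def lower_bound(rel: tuple[int, ...]) -> int:
    """Admissible lower bound on the reversal distance to the identity."""
    n = len(rel)
    b = _breakpoints_tuple(rel)
    return max((b + 1) // 2, n + 1 - cycle_count(rel))


# ---------------------------------------------------------------------------
# exact search


@dataclass
class SearchStats:
    nodes_expanded: int = 0
    pruning_hits: int = 0
    thresholds_tried: int = 0


def _reversals(n: int) -> list[tuple[int, int]]:
    """All reversal index pairs in canonical lexicographic order (0-based,
    half-open)."""
    return [(i, j) for i in range(n) for j in range(i + 1, n + 1)]


def _apply(rel: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    return rel[:i] + tuple(-x for x in reversed(rel[i:j])) + rel[j:]


_IDENTITY_CACHE: dict[int, tuple[int, ...]] = {}


def _ident(n: int) -> tuple[int, ...]:
    if n not in _IDENTITY_CACHE:
        _IDENTITY_CACHE[n] = tuple(range(1, n + 1))
    return _IDENTITY_CACHE[n]


def _check_cap(n: int, max_n: int) -> None:
    if n > max_n:
        raise CapExceededError(
            f"refusing to search arrangements of {n} blocks "
            f"(cap is {max_n} blocks; raise max_n explicitly if you mean it)"
        )


def reversal_distance(
    arr: Arrangement,
    target: Arrangement,
    max_n: int = DEFAULT_MAX_N,
    stats: SearchStats | None = None,
) -> int:
    """Length of a shortest reversal sequence transforming ``arr`` into
    ``target``.

    Exact, via iterative-deepening DFS pruned with :func:`lower_bound`.
    Refuses arrangements larger than ``max_n`` blocks to prevent runaway
    search.
    """
    _check_cap(arr.n, max_n)
    rel = relative_arrangement(arr, target).blocks
    n = len(rel)
    ident = _ident(n)
    if rel == ident:
        return 0
    revs = _reversals(n)
    stats = stats if stats is not None else SearchStats()

    def dfs(state: tuple[int, ...], g: int, threshold: int) -> bool:
        stats.nodes_expanded += 1
        for i, j in revs:
            child = _apply(state, i, j)
            if child == ident:
                if g + 1 <= threshold:
                    return True
                continue
            if g + 1 + lower_bound(child) > threshold:
                stats.pruning_hits += 1
                continue
            if dfs(child, g + 1, threshold):
                return True
        return False

    threshold = lower_bound(rel)
    while True:
        stats.thresholds_tried += 1
        if dfs(rel, 0, threshold):
            return threshold
        threshold += 1


@dataclass(frozen=True)
class ScenarioSet:
    """Result of exhaustive minimal-scenario enumeration.

    ``truncated`` is set when the enumeration stopped at ``max_scenarios``;
    in that case ``scenarios`` holds the first ``max_scenarios`` scenarios in
    canonical order and the true count is larger.
    """

    scenarios: tuple[Scenario, ...]
    distance: int
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)


def minimal_scenarios(
    arr: Arrangement,
    target: Arrangement,
    max_scenarios: int = 10_000,
    max_n: int = DEFAULT_MAX_N,
) -> ScenarioSet:
    """All distinct reversal sequences of minimal length from ``arr`` to
    ``target``, in canonical order (lexicographic by ``(start, end)`` per
    step).

    A sequence of exactly ``reversal_distance(arr, target)`` reversals can
    never revisit an arrangement (a revisit would shortcut to a shorter
    sequence), so plain bounded DFS enumerates each scenario exactly once.
    """
    if max_scenarios <= 0:
        raise InputError(f"max_scenarios must be positive, got {max_scenarios}")
    _check_cap(arr.n, max_n)
    d = reversal_distance(arr, target, max_n=max_n)
    rel = relative_arrangement(arr, target).blocks
    n = len(rel)
    ident = _ident(n)
    revs = _reversals(n)
    found: list[tuple[tuple[int, int], ...]] = []
    truncated = False

    def dfs(state: tuple[int, ...], path: list[tuple[int, int]]) -> bool:
        """Returns False when the cap was hit and enumeration must stop."""
        if state == ident and len(path) == d:
            found.append(tuple(path))
            return len(found) < max_scenarios
        remaining = d - len(path)
        if remaining == 0:
            return True
        for i, j in revs:
            child = _apply(state, i, j)
            if lower_bound(child) > remaining - 1:
                continue
            path.append((i, j))
            ok = dfs(child, path)
            path.pop()
            if not ok:
                return False
        return True

    if d == 0:
        scenarios = (Scenario.from_steps(arr, ()),)
        return ScenarioSet(scenarios, 0, False)
    truncated = not dfs(rel, [])
    scenarios = tuple(
        Scenario.from_steps(
            arr, (Reversal(i + 1, j) for i, j in steps), name=target.name
        )
        for steps in found
    )
    return ScenarioSet(scenarios, d, truncated)


# ---------------------------------------------------------------------------
# greedy heuristic


def _strips(rel: tuple[int, ...]) -> list[tuple[int, int]]:
    """Maximal breakpoint-free runs as 0-based half-open index intervals."""
    n = len(rel)
    bounds = [0] + [k for k in range(1, n) if rel[k] - rel[k - 1] != 1] + [n]
    return [(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def greedy_scenario(arr: Arrangement, target: Arrangement) -> Scenario:
    """A valid (not necessarily minimal) scenario built by greedy breakpoint
    reduction.

    At each step the reversal that maximally reduces the framed breakpoint
    count is applied; ties prefer the shorter span, then the leftmost start.
    When no reversal reduces the count (which can only happen while every
    block is positively oriented relative to the target), the leftmost
    maximal strip whose flip does not increase the count is reversed, which
    creates a negatively oriented strip; a breakpoint-removing reversal then
    always exists, so the loop terminates.  The result length is always >=
    the exact reversal distance.
    """
    rel = relative_arrangement(arr, target).blocks
    n = len(rel)
    ident = _ident(n)
    steps: list[Reversal] = []
    guard = 2 * (n + 2) * (_breakpoints_tuple(rel) + 1) + 10
    while rel != ident:
        if len(steps) > guard:  # pragma: no cover - theoretical safety net
            raise RuntimeError("greedy failed to terminate; this is a bug")
        b0 = _breakpoints_tuple(rel)
        best: tuple[int, int, int] | None = None  # (-delta, span, start)
        best_ij: tuple[int, int] | None = None
        for i, j in _reversals(n):
            delta = b0 - _breakpoints_tuple(_apply(rel, i, j))
            key = (-delta, j - i, i)
            if best is None or key < best:
                best = key
                best_ij = (i, j)
        assert best is not None and best_ij is not None
        if -best[0] > 0:
            i, j = best_ij
        else:
            # strip-flip fallback: leftmost maximal strip whose reversal
            # keeps the breakpoint count (both its boundaries are already
            # breakpoints, so the count can only stay or drop)
            for i, j in _strips(rel):
                if _breakpoints_tuple(_apply(rel, i, j)) <= b0:
                    break
            else:  # pragma: no cover - cannot happen for unsorted input
                raise RuntimeError("no admissible strip flip; this is a bug")
        rel = _apply(rel, i, j)
        steps.append(Reversal(i + 1, j))
    return Scenario.from_steps(arr, steps, name=target.name)


# ---------------------------------------------------------------------------
# rendering


def render_scenario(sc: Scenario, style: str = "compact") -> str:
    """Render a scenario as text.

    ``compact`` prints the arrow-separated arrangements; ``table`` adds one
    line per step with the reversal interval applied.
    """
    if style == "compact":
        return " → ".join(str(a) for a in sc.intermediates)
    if style == "table":
        lines = [f"step 0: {sc.intermediates[0]}"]
        for k, rev in enumerate(sc.steps, start=1):
            lines.append(
                f"step {k}: {sc.intermediates[k]}   "
                f"[reversal {rev.start}..{rev.end}]"
            )
        return "\n".join(lines)
    raise InputError(f"unknown render style {style!r}")


# ---------------------------------------------------------------------------
# exhaustive BFS cross-check


def rank_arrangement(blocks: tuple[int, ...]) -> int:
    """Rank of a signed permutation in ``[0, n! * 2**n)``.

    Lehmer code of the absolute permutation times ``2**n`` plus the sign
    bits, most significant bit first.  Used to index BFS distance tables.
    """
    n = len(blocks)
    a = [abs(b) - 1 for b in blocks]
    r = 0
    for i in range(n):
        smaller = sum(1 for x in a[i + 1 :] if x < a[i])
        r = r * (n - i) + smaller
    s = 0
    for b in blocks:
        s = (s << 1) | (1 if b < 0 else 0)
    return (r << n) | s


def _rank_batch(perms: np.ndarray) -> np.ndarray:
    n = perms.shape[1]
    a = np.abs(perms)
    r = np.zeros(len(perms), dtype=np.int64)
    for i in range(n):
        smaller = (a[:, i + 1 :] < a[:, i : i + 1]).sum(
            axis=1, dtype=np.int64
        )
        r = r * (n - i) + smaller
    s = np.zeros(len(perms), dtype=np.int64)
    neg = perms < 0
    for i in range(n):
        s = (s << 1) | neg[:, i]
    return (r << n) | s


def bfs_distance_table(n: int) -> np.ndarray:
    """Exact reversal distance from the identity to every signed permutation
    of ``n`` blocks, by breadth-first search over the full reversal graph.

    Returns a ``uint8`` array of length ``n! * 2**n`` indexed by
    :func:`rank_arrangement`.  Independent of the iterative-deepening
    solver: useful as an exhaustive cross-check (the whole space for n = 8
    is ~10.3 million states and fits in memory).
    """
    if n > 9:
        raise CapExceededError(
            f"full BFS over signed permutations of {n} blocks is infeasible"
        )
    size = math.factorial(n) * 2**n
    dist = np.full(size, 255, dtype=np.uint8)
    ident = np.arange(1, n + 1, dtype=np.int8)[None, :]
    dist[_rank_batch(ident)] = 0
    frontier = ident
    d = 0
    # within one reversal a batch of distinct states maps to distinct
    # neighbours (reversals are bijections), and cross-reversal duplicates
    # are filtered by the immediate dist update, so no deduplication pass
    # is needed
    while len(frontier):
        new_states: list[np.ndarray] = []
        for i in range(n):
            for j in range(i + 1, n + 1):
                nb = frontier.copy()
                nb[:, i:j] = -frontier[:, i:j][:, ::-1]
                r = _rank_batch(nb)
                mask = dist[r] == 255
                if mask.any():
                    dist[r[mask]] = d + 1
                    new_states.append(nb[mask])
        d += 1
        if not new_states:
            break
        frontier = np.concatenate(new_states)
    return dist
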