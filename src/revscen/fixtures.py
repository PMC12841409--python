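"""The packaged *Anopheles* X-chromosome worked example.

The bundle holds four arrangements of eight syntenic blocks — the ancestral
order of the outgroup reference (*An. atroparvus*), the X1 arrangement
shared by *An. messeae* and *An. daciae*, and the species-specific X2
(*An. messeae*) and X0 (*An. daciae*) arrangements — together with the
breakpoint-region marker table and the junction constraints that pin the two
polymorphic inversions onto X1.

The ancestral order and X1 are printed facts; the signed orders of X2 and X0
are derived here by translating each inversion's mapped junction pair into a
reversal on X1 (there is exactly one reversal with those endpoints), which
is recorded in the per-item provenance notes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .distance import minimal_scenarios, render_scenario, reversal_distance
from .errors import DerivedJunctionError, IntegrityError, InputError
from .io import read_marker_table
from .signed_perm import Arrangement, apply_reversal, parse_arrangements
from .synteny import (
    BreakpointRegion,
    SyntenyMap,
    ancestral_junction,
    build_partition,
    disrupted_blocks,
    gap_bp,
    involved_blocks,
    reversal_from_junctions,
)

__all__ = ["FixtureBundle", "InversionConstraint", "load_fixture", "run_report"]

FIXTURES = ("anopheles_x",)


@dataclass(frozen=True)
class InversionConstraint:
    """A polymorphic inversion declared by its two junctions on a carrier
    arrangement: each junction is either an intact ancestral boundary
    (``("edge", k)``) or an explicit derived adjacency (``("pair", (a, b))``).
    """

    name: str
    on: str
    left: tuple
    right: tuple
    result: str

    def resolve_junction(self, arr: Arrangement, which: str):
        kind, value = getattr(self, which)
        if kind == "edge":
            return ancestral_junction(arr, value)
        return value


@dataclass(frozen=True)
class FixtureBundle:
    name: str
    arrangements: dict[str, Arrangement]
    regions: tuple[BreakpointRegion, ...]
    inversions: tuple[InversionConstraint, ...]
    provenance: dict[str, str] = field(default_factory=dict)

    def arrangement(self, key: str) -> Arrangement:
        try:
            return self.arrangements[key]
        except KeyError:
            raise InputError(f"fixture has no arrangement {key!r}") from None

    @property
    def span(self) -> tuple[float, float]:
        return (0.0, float(self.arrangement("ancestral").n))


def _parse_junction(text: str) -> tuple:
    kind, _, rest = text.partition(":")
    if kind == "edge":
        return ("edge", int(rest))
    if kind == "pair":
        a, b = rest.split(",")
        return ("pair", (int(a), int(b)))
    raise IntegrityError(f"unknown junction spec {text!r}")


def _data_dir(name: str) -> Path:
    if name not in FIXTURES:
        raise InputError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        )
    return Path(str(resources.files("revscen").joinpath("data", name)))


def load_fixture(name: str = "anopheles_x") -> FixtureBundle:
    """Load and integrity-check a packaged fixture."""
    root = _data_dir(name)
    arrangements = parse_arrangements((root / "arrangements.txt").read_text())
    regions = read_marker_table(root / "markers.tsv")
    constraints = []
    with open(root / "inversions.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            constraints.append(
                InversionConstraint(
                    name=row["inversion"],
                    on=row["on"],
                    left=_parse_junction(row["left_junction"]),
                    right=_parse_junction(row["right_junction"]),
                    result=row["result"],
                )
            )
    bundle = FixtureBundle(
        name=name,
        arrangements=arrangements,
        regions=regions,
        inversions=tuple(constraints),
        provenance={
            "ancestral": "printed: outgroup gene order, blocks 1..8",
            "X1": "printed: signed order from the two nested fixed inversions",
            "X2": "derived: unique reversal of X1 matching the mapped "
            "junction pair (ancestral edge 5|6, derived junction -2|7)",
            "X0": "derived: unique reversal of X1 matching the mapped "
            "junction pair (ancestral edges 3|4 and 7|8)",
            "markers": "printed: flanking-gene coordinates on the reference "
            "assembly; fixed-inversion boundaries kept abstract",
        },
    )
    _check_integrity(bundle)
    return bundle


def _check_integrity(bundle: FixtureBundle) -> None:
    required = {"ancestral", "X1", "X2", "X0"}
    missing = required - set(bundle.arrangements)
    if missing:
        raise IntegrityError(f"fixture lacks arrangements {sorted(missing)}")
    anc = bundle.arrangement("ancestral")
    if not anc.is_identity() or anc.n != 8:
        raise IntegrityError("ancestral arrangement must be the identity on 8")
    x1 = bundle.arrangement("X1")
    if x1.blocks != (1, -6, -5, 3, 4, -2, 7, 8):
        raise IntegrityError(f"unexpected X1 arrangement: {x1}")
    # each declared inversion must be the unique single reversal taking its
    # carrier to the stored result
    for con in bundle.inversions:
        carrier = bundle.arrangement(con.on)
        rev = reversal_from_junctions(
            carrier,
            con.resolve_junction(carrier, "left"),
            con.resolve_junction(carrier, "right"),
        )
        got = apply_reversal(carrier, rev)
        want = bundle.arrangement(con.result)
        if got.blocks != want.blocks:
            raise IntegrityError(
                f"inversion {con.name}: junction constraints give {got}, "
                f"stored arrangement is {want}"
            )


def coarse_partition(bundle: FixtureBundle) -> SyntenyMap:
    """Partition from the fixed-inversion breakpoint regions only."""
    fixed = [br for br in bundle.regions if br.category == "fixed"]
    return build_partition(fixed, span=bundle.span)


def full_partition(bundle: FixtureBundle) -> SyntenyMap:
    """Partition from fixed plus polymorphic breakpoint regions."""
    return build_partition(bundle.regions, span=bundle.span)


def run_report(bundle: FixtureBundle) -> dict:
    """Deterministic structured report over a fixture bundle.

    Every number is produced by an operation in the core modules; the report
    only assembles them.
    """
    anc = bundle.arrangement("ancestral")
    x1 = bundle.arrangement("X1")

    distances = {
        "ancestral->X1": reversal_distance(anc, x1),
    }
    for con in bundle.inversions:
        carrier = bundle.arrangement(con.on)
        result = bundle.arrangement(con.result)
        distances[f"{con.on}->{con.result}"] = reversal_distance(
            carrier, result
        )
        distances[f"ancestral->{con.result}"] = reversal_distance(anc, result)

    sset = minimal_scenarios(anc, x1)
    coarse = coarse_partition(bundle)
    full = full_partition(bundle)

    inversions = {}
    for con in bundle.inversions:
        carrier = bundle.arrangement(con.on)
        rev = reversal_from_junctions(
            carrier,
            con.resolve_junction(carrier, "left"),
            con.resolve_junction(carrier, "right"),
        )
        inv_blocks = involved_blocks(carrier, rev)
        new_bounds = [
            float(value)
            for kind, value in (con.left, con.right)
            if kind == "edge"
        ]
        inversions[con.name] = {
            "carrier": con.on,
            "reversal": [rev.start, rev.end],
            "result": str(bundle.arrangement(con.result)),
            "involved_blocks": sorted(inv_blocks),
            "involved_count": len(inv_blocks),
            "new_ancestral_boundaries": new_bounds,
            "disrupted_coarse_blocks": disrupted_blocks(coarse, new_bounds),
        }

    gaps = {}
    for br in bundle.regions:
        if len(br.flanks) < 2:
            continue
        try:
            gaps[br.name] = {"gap_bp": gap_bp(br), "derived_junction": False}
        except DerivedJunctionError:
            gaps[br.name] = {"gap_bp": None, "derived_junction": True}

    return {
        "fixture": bundle.name,
        "distances": distances,
        "minimal_scenarios_ancestral_to_X1": {
            "count": len(sset),
            "multiple_scenarios": len(sset) > 1,
            "scenarios": [render_scenario(sc) for sc in sset],
        },
        "block_count_coarse": coarse.n_blocks,
        "block_count_full": full.n_blocks,
        "inversions": inversions,
        "breakpoint_region_gaps": gaps,
        "scenario_text": render_scenario(sset.scenarios[0])
        if len(sset)
        else str(anc),
        "provenance": dict(sorted(bundle.provenance.items())),
    }
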