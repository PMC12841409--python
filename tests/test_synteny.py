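"""Breakpoint regions, block partitions, involved/disrupted statistics."""

import numpy as np
import pytest

from revscen.errors import (
    ConstraintError,
    DerivedJunctionError,
    InputError,
)
from revscen.signed_perm import Arrangement, Reversal, apply_reversal
from revscen.synteny import (
    BreakpointRegion,
    GeneMarker,
    ancestral_junction,
    build_partition,
    disrupted_blocks,
    gap_bp,
    involved_blocks,
    is_derived_junction,
    reversal_from_junctions,
)

from conftest import random_arrangement


def mk(gene, start, end, strand="+"):
    return GeneMarker(gene, start, end, strand)


@pytest.fixture
def fixed_brs():
    return [
        BreakpointRegion("BRI", ancestral_edge=1, category="fixed"),
        BreakpointRegion("BRII", ancestral_edge=2, category="fixed"),
        BreakpointRegion("BRIII", ancestral_edge=4, category="fixed"),
        BreakpointRegion("BRIV", ancestral_edge=6, category="fixed"),
    ]


@pytest.fixture
def polymorphic_brs():
    return [
        BreakpointRegion(
            "X2 distal",
            mk("AATE009941", 13_261_242, 13_265_420, "+"),
            mk("AATE005475", 13_236_449, 13_246_292, "-"),
            ancestral_edge=5,
        ),
        BreakpointRegion(
            "X2 proximal",
            mk("AATE016042", 1_465_925, 1_468_608, "-"),
            mk("AATE009858", 14_520_988, 14_521_746, "+"),
            colocated_with="BRIV",
        ),
        BreakpointRegion(
            "X0 distal",
            mk("AATE021012", 4_398_009, 4_404_032, "-"),
            mk("AATE013154", 4_571_860, 4_577_721, "-"),
            ancestral_edge=3,
        ),
        BreakpointRegion(
            "X0 proximal",
            mk("AATE003340", 17_252_047, 17_256_383, "+"),
            mk("AATE018776", 17_260_494, 17_265_377, "-"),
            ancestral_edge=7,
        ),
    ]


class TestMarkers:
    def test_span_and_strand_validated(self):
        with pytest.raises(InputError, match="start"):
            GeneMarker("g", 10, 5, "+")
        with pytest.raises(InputError, match="strand"):
            GeneMarker("g", 1, 5, "?")

    def test_flanks_must_differ(self):
        with pytest.raises(InputError, match="distinct"):
            BreakpointRegion("r", mk("g", 1, 5), mk("g", 10, 20))


class TestPartition:
    def test_fixed_regions_give_five_blocks(self, fixed_brs):
        smap = build_partition(fixed_brs, span=(0, 8))
        assert smap.n_blocks == 5
        assert smap.boundaries == (1.0, 2.0, 4.0, 6.0)

    def test_full_set_gives_eight_blocks(self, fixed_brs, polymorphic_brs):
        smap = build_partition(fixed_brs + polymorphic_brs, span=(0, 8))
        assert smap.n_blocks == 8
        # the colocated X2 proximal region shares BRIV's boundary
        by_pos = dict(smap.boundary_sources)
        assert "X2 proximal" in by_pos[6.0] and "BRIV" in by_pos[6.0]

    def test_empty_region_set_gives_one_block(self):
        assert build_partition([]).n_blocks == 1

    def test_invariant_to_input_order_and_coloc_role_swap(
        self, fixed_brs, polymorphic_brs
    ):
        base = build_partition(fixed_brs + polymorphic_brs, span=(0, 8))
        shuffled = build_partition(
            list(reversed(polymorphic_brs)) + fixed_brs, span=(0, 8)
        )
        assert shuffled.boundaries == base.boundaries
        # point the colocation arrow the other way round
        flipped = [
            BreakpointRegion("BRI", ancestral_edge=1, category="fixed"),
            BreakpointRegion("BRII", ancestral_edge=2, category="fixed"),
            BreakpointRegion("BRIII", ancestral_edge=4, category="fixed"),
            BreakpointRegion(
                "BRIV", ancestral_edge=6, category="fixed",
                colocated_with="X2 proximal",
            ),
            BreakpointRegion(
                "X2 proximal",
                mk("AATE016042", 1_465_925, 1_468_608, "-"),
                mk("AATE009858", 14_520_988, 14_521_746, "+"),
            ),
        ] + [br for br in polymorphic_brs if br.name != "X2 proximal"]
        assert build_partition(flipped, span=(0, 8)).boundaries == base.boundaries

    def test_dangling_colocation_rejected(self):
        br = BreakpointRegion("solo", colocated_with="ghost", ancestral_edge=1)
        with pytest.raises(ConstraintError, match="ghost"):
            build_partition([br])

    def test_conflicting_colocated_boundaries_rejected(self):
        a = BreakpointRegion("a", ancestral_edge=2)
        b = BreakpointRegion("b", ancestral_edge=5, colocated_with="a")
        with pytest.raises(ConstraintError, match="conflicting"):
            build_partition([a, b])


class TestGaps:
    def test_x0_distal_inner_gap(self, polymorphic_brs):
        x0d = next(b for b in polymorphic_brs if b.name == "X0 distal")
        assert gap_bp(x0d) == 4_571_860 - 4_404_032 == 167_828

    def test_x2_distal_gap_uses_coordinate_order_not_roles(self, polymorphic_brs):
        # the distal flank lies at larger coordinates than the proximal one
        x2d = next(b for b in polymorphic_brs if b.name == "X2 distal")
        assert gap_bp(x2d) == 13_261_242 - 13_246_292 == 14_950

    def test_touching_genes_have_zero_gap(self):
        br = BreakpointRegion("t", mk("a", 100, 200), mk("b", 200, 300))
        assert gap_bp(br) == 0

    def test_overlapping_genes_reported_negative(self):
        br = BreakpointRegion("o", mk("a", 100, 250), mk("b", 200, 300))
        assert gap_bp(br) == -50

    def test_derived_junction_gap_suppressed(self, polymorphic_brs):
        x2p = next(b for b in polymorphic_brs if b.name == "X2 proximal")
        assert is_derived_junction(x2p)
        with pytest.raises(DerivedJunctionError, match="X2 proximal"):
            gap_bp(x2p)

    def test_missing_coordinates_rejected(self):
        br = BreakpointRegion("abstract", ancestral_edge=3)
        with pytest.raises(InputError, match="flank"):
            gap_bp(br)


class TestJunctions:
    def test_x2_reversal_from_junctions(self, x1, x2):
        rev = reversal_from_junctions(x1, (-6, -5), (-2, 7))
        assert rev == Reversal(3, 6)
        assert apply_reversal(x1, rev).blocks == x2.blocks

    def test_x0_reversal_from_ancestral_edges(self, x1, x0):
        left = ancestral_junction(x1, 3)
        right = ancestral_junction(x1, 7)
        assert (left, right) == ((3, 4), (7, 8))
        rev = reversal_from_junctions(x1, left, right)
        assert rev == Reversal(5, 7)
        assert apply_reversal(x1, rev).blocks == x0.blocks

    def test_junction_orientation_insensitive(self, x1):
        assert reversal_from_junctions(x1, (5, 6), (-2, 7)) == Reversal(3, 6)

    def test_chromosome_ends_as_junctions(self, x1):
        assert reversal_from_junctions(x1, "start", "end") == Reversal(1, 8)

    def test_absent_adjacency_reported(self, x1):
        with pytest.raises(ConstraintError, match=r"\(3, 7\)"):
            reversal_from_junctions(x1, (3, 7), "end")

    def test_coincident_junctions_rejected(self, x1):
        with pytest.raises(InputError, match="zero-length"):
            reversal_from_junctions(x1, (-6, -5), (-6, -5))

    def test_wrong_order_rejected(self, x1):
        with pytest.raises(InputError, match="precede"):
            reversal_from_junctions(x1, (-2, 7), (-6, -5))

    def test_broken_ancestral_edge_reported(self, x1):
        with pytest.raises(ConstraintError, match="1|2"):
            ancestral_junction(x1, 1)  # broken by the outer fixed inversion


class TestBlockStatistics:
    def test_involved_blocks_worked_examples(self, x1):
        assert involved_blocks(x1, Reversal(3, 6)) == {2, 3, 4, 5}
        assert involved_blocks(x1, Reversal(5, 7)) == {2, 4, 7}

    def test_single_position_reversal_is_singleton(self, x1):
        assert involved_blocks(x1, Reversal(2, 2)) == {6}

    def test_involved_size_equals_span(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            arr = random_arrangement(rng, n)
            i = int(rng.integers(1, n + 1))
            j = int(rng.integers(i, n + 1))
            assert len(involved_blocks(arr, Reversal(i, j))) == j - i + 1

    def test_disrupted_counts_worked_examples(self, fixed_brs):
        coarse = build_partition(fixed_brs, span=(0, 8))
        assert disrupted_blocks(coarse, [3.0, 7.0]) == 2  # X0 boundaries
        assert disrupted_blocks(coarse, [5.0]) == 1  # X2 distal only
        assert disrupted_blocks(coarse, []) == 0

    def test_disrupted_never_exceeds_new_boundary_count(self, fixed_brs):
        coarse = build_partition(fixed_brs, span=(0, 8))
        rng = np.random.default_rng(43)
        for _ in range(50):
            k = int(rng.integers(0, 5))
            pts = list(rng.uniform(0, 8, size=k))
            assert disrupted_blocks(coarse, pts) <= k

    def test_boundary_outside_span_rejected(self, fixed_brs):
        coarse = build_partition(fixed_brs, span=(0, 8))
        with pytest.raises(InputError, match="outside"):
            disrupted_blocks(coarse, [9.5])
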