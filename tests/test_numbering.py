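"""FDI numbering: arch geometry, quadrant/position assignment, gap inference,
deciduous mapping, and the panoramic/sequential pipelines."""

import numpy as np
import pytest

from dentnum.detections import DentitionLayout, DetectionBox, ToothClass
from dentnum.errors import (
    DegenerateArchError,
    InvalidParameterError,
    QuadrantOverflowError,
    WrongModalityError,
)
from dentnum.numbering import (
    FDICode,
    NumberingParams,
    ToothAssignment,
    all_fdi_codes,
    assign_deciduous,
    assign_quadrant,
    estimate_arch_center,
    infer_missing_in_quadrant,
    number_panoramic,
    number_sequential,
    order_positions,
    presence_from_assignments,
)
from dentnum.raster import Modality
from dentnum.synthetic import ArchSpec, generate_layout, recovery_rate


def box(cx, cy, w=30.0, h=80.0, cls=ToothClass.PERMANENT):
    return DetectionBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, cls)


def quadrant_row(x_mid, widths, y=200.0, side=1, missing=()):
    """Abutting boxes outward from the midline; ``missing`` slots left empty."""
    boxes, x = [], x_mid
    for i, w in enumerate(widths, start=1):
        x_next = x + side * w
        if i not in missing:
            boxes.append(DetectionBox(min(x, x_next), y - 40, max(x, x_next), y + 40))
        x = x_next
    return boxes


class TestFDICode:
    def test_deciduous_positions_capped_at_5(self):
        with pytest.raises(InvalidParameterError):
            FDICode(5, 6)
        assert FDICode(5, 5).is_deciduous

    def test_enumeration_covers_52_codes_in_fdi_order(self):
        codes = all_fdi_codes()
        assert len(codes) == 52
        assert str(codes[0]) == "11" and str(codes[31]) == "48" and str(codes[-1]) == "85"

    def test_assignment_class_must_match_code_range(self):
        b = box(100, 100, cls=ToothClass.DECIDUOUS)
        with pytest.raises(InvalidParameterError):
            ToothAssignment(b, FDICode(1, 1))


class TestArchCenter:
    def test_symmetric_full_arch_center_recovered_within_1px(self):
        layout, _ = generate_layout(ArchSpec())
        x_mid, y_mid = estimate_arch_center(layout)
        assert abs(x_mid - 600.0) <= 1.0
        assert 250.0 < y_mid < 450.0

    def test_y_mid_is_midpoint_between_two_boxes(self):
        layout = DentitionLayout(Modality.PANO, 640, 640, [box(300, 200), box(320, 400)])
        _, y_mid = estimate_arch_center(layout)
        assert y_mid == 300.0

    def test_single_jaw_raises_degenerate_arch_naming_the_jaw(self):
        upper_only = DentitionLayout(
            Modality.PANO, 640, 640, [box(200, 100), box(250, 105), box(300, 102)]
        )
        with pytest.raises(DegenerateArchError) as exc:
            estimate_arch_center(upper_only)
        assert exc.value.jaw_found == "upper"

    def test_midline_robust_to_one_sided_missing_teeth(self):
        # a single missing left tooth shifts a plain median onto the right
        # central incisor; the symmetry estimator must not be fooled
        present = frozenset({10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9)} - {13})
        layout, _ = generate_layout(ArchSpec(present_permanent=present))
        x_mid, _ = estimate_arch_center(layout)
        assert abs(x_mid - 600.0) <= 1.0


class TestQuadrantAndOrdering:
    CENTER = (320.0, 300.0)

    @pytest.mark.parametrize(
        "cx,cy,cls,expected",
        [
            (200, 200, ToothClass.PERMANENT, 1),
            (400, 200, ToothClass.PERMANENT, 2),
            (400, 400, ToothClass.PERMANENT, 3),
            (200, 400, ToothClass.PERMANENT, 4),
            (200, 200, ToothClass.DECIDUOUS, 5),
            (400, 400, ToothClass.DECIDUOUS, 7),
        ],
    )
    def test_clockwise_quadrants_and_deciduous_offset(self, cx, cy, cls, expected):
        assert assign_quadrant(box(cx, cy, cls=cls), self.CENTER) == expected

    def test_box_exactly_on_midline_goes_left(self):
        assert assign_quadrant(box(320, 200), self.CENTER) == 1
        assert assign_quadrant(box(320, 400), self.CENTER) == 4

    def test_order_is_ascending_distance_from_midline(self):
        boxes = [box(300, 200), box(250, 200), box(200, 200)]
        ordered = order_positions(boxes, x_mid=320.0)
        assert [b.cx for b in ordered] == [300, 250, 200]

    def test_permuted_quadrant_always_recovers_anatomical_order(self, rng):
        base = quadrant_row(320.0, [28, 26, 30, 32, 32, 46, 44, 42], side=-1)
        for _ in range(5):
            perm = [base[i] for i in rng.permutation(len(base))]
            assert order_positions(perm, 320.0) == base


class TestGapInference:
    WIDTHS = [28, 26, 30, 32, 32, 46, 44]

    def test_abutting_teeth_get_consecutive_positions(self):
        boxes = quadrant_row(320.0, self.WIDTHS, side=1)
        positions, missing = infer_missing_in_quadrant(boxes, 320.0)
        assert positions == [1, 2, 3, 4, 5, 6, 7]
        assert missing == []

    def test_single_deleted_tooth_leaves_its_position_missing(self):
        boxes = quadrant_row(320.0, self.WIDTHS + [42], side=1, missing={5})
        positions, missing = infer_missing_in_quadrant(boxes, 320.0)
        assert positions == [1, 2, 3, 4, 6, 7, 8]
        assert missing == [5]

    def test_double_gap_yields_two_consecutive_missing(self):
        priors = {i + 1: w for i, w in enumerate(self.WIDTHS + [42])}
        params = NumberingParams(expected_width_source="per_position_prior", width_priors=priors)
        boxes = quadrant_row(320.0, self.WIDTHS + [42], side=1, missing={5, 6})
        positions, missing = infer_missing_in_quadrant(boxes, 320.0, params)
        assert missing == [5, 6]
        assert positions == [1, 2, 3, 4, 7, 8]

    def test_midline_gap_marks_central_incisor_missing(self):
        boxes = quadrant_row(320.0, self.WIDTHS, side=-1, missing={1})
        positions, missing = infer_missing_in_quadrant(boxes, 320.0)
        assert positions[0] == 2 and missing == [1]

    def test_trailing_positions_reported_only_with_third_molar_flag(self):
        boxes = quadrant_row(320.0, self.WIDTHS[:4], side=1)
        _, missing_default = infer_missing_in_quadrant(boxes, 320.0)
        assert missing_default == []
        params = NumberingParams(include_third_molars_in_gaps=True)
        _, missing_flagged = infer_missing_in_quadrant(boxes, 320.0, params)
        assert missing_flagged == [5, 6, 7, 8]

    def test_more_than_eight_boxes_overflows(self):
        boxes = quadrant_row(320.0, [30] * 9, side=1)
        with pytest.raises(QuadrantOverflowError):
            infer_missing_in_quadrant(boxes, 320.0)

    def test_overflow_from_a_false_gap_is_repaired(self):
        # 8 true teeth, but one span is widened just past the gap threshold
        boxes = quadrant_row(320.0, [30] * 8, side=1)
        shifted = [
            DetectionBox(b.x1 + (17 if i >= 4 else 0), b.y1, b.x2 + (17 if i >= 4 else 0), b.y2)
            for i, b in enumerate(boxes)
        ]
        positions, missing = infer_missing_in_quadrant(shifted, 320.0)
        assert positions == [1, 2, 3, 4, 5, 6, 7, 8]
        assert missing == []


class TestDeciduous:
    def _arch(self, dec_codes, perm_missing=frozenset()):
        perm = frozenset({10 * q + p for q in (1, 2, 3, 4) for p in range(1, 8)} - perm_missing)
        spec = ArchSpec(present_permanent=perm, present_deciduous=frozenset(dec_codes))
        return generate_layout(spec)

    def test_box_aligned_with_permanent_11_gets_code_51(self):
        layout, truth = self._arch({51})
        result = number_panoramic(layout)
        dec = [a for a in result.assignments if a.code.is_deciduous]
        assert [str(a.code) for a in dec] == ["51"]

    def test_alignment_with_positions_3_and_5_gives_53_and_55(self):
        layout, _ = self._arch({53, 55})
        result = number_panoramic(layout)
        assert sorted(str(a.code) for a in result.assignments if a.code.is_deciduous) == ["53", "55"]

    def test_two_boxes_near_one_permanent_tooth_get_distinct_codes(self):
        center = (320.0, 300.0)
        perm = [ToothAssignment(box(350, 200, w=30), FDICode(2, 1))]
        d1 = box(352, 180, w=24, cls=ToothClass.DECIDUOUS)
        d2 = box(378, 180, w=24, cls=ToothClass.DECIDUOUS)
        assignments, unassigned = assign_deciduous([d1, d2], perm, center)
        codes = sorted(str(a.code) for a in assignments)
        assert len(set(codes)) == 2 and not unassigned
        inner = next(a for a in assignments if a.box is d1)
        outer = next(a for a in assignments if a.box is d2)
        assert outer.code.position == inner.code.position + 1

    def test_jaw_without_permanent_teeth_falls_back_to_geometric_order(self):
        center = (320.0, 300.0)
        dec = [box(280, 200, cls=ToothClass.DECIDUOUS), box(240, 200, cls=ToothClass.DECIDUOUS)]
        with pytest.warns(UserWarning, match="geometric ordering"):
            assignments, _ = assign_deciduous(dec, [], center)
        assert sorted(str(a.code) for a in assignments) == ["51", "52"]


class TestPanoramicPipeline:
    def test_full_permanent_dentition_recovers_all_32_codes(self):
        layout, truth = generate_layout(ArchSpec())
        result = number_panoramic(layout)
        assert recovery_rate(layout, truth, result) == 1.0
        assert result.missing == []
        assert sum(result.presence.values()) == 32

    def test_deleted_25_is_inferred_missing(self):
        present = frozenset({10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9)} - {25})
        layout, truth = generate_layout(ArchSpec(present_permanent=present))
        result = number_panoramic(layout)
        assert [str(c) for c in result.missing] == ["25"]
        assert result.presence[FDICode(2, 5)] == 0
        assert recovery_rate(layout, truth, result) == 1.0

    def test_no_duplicate_codes_over_random_layouts(self, rng):
        for _ in range(20):
            perm = {
                10 * q + p
                for q in (1, 2, 3, 4)
                for p in range(1, 9)
                if rng.random() > 0.2
            }
            if not perm:
                continue
            spec = ArchSpec(
                present_permanent=frozenset(perm),
                jitter_frac=0.1,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            layout, _ = generate_layout(spec)
            try:
                result = number_panoramic(layout)
            except DegenerateArchError:
                continue
            codes = [a.code for a in result.assignments]
            assert len(codes) == len(set(codes))

    def test_positions_increase_monotonically_with_midline_distance(self):
        layout, _ = generate_layout(ArchSpec(jitter_frac=0.05, seed=3))
        result = number_panoramic(layout)
        x_mid = result.arch_center[0]
        by_quadrant = {}
        for a in result.assignments:
            by_quadrant.setdefault(a.code.quadrant, []).append(a)
        for items in by_quadrant.values():
            items.sort(key=lambda a: a.code.position)
            dists = [abs(a.box.cx - x_mid) for a in items]
            assert dists == sorted(dists)

    def test_mirrored_layout_swaps_left_right_quadrants(self):
        layout, truth = generate_layout(ArchSpec(seed=1))
        result = number_panoramic(layout)
        w = layout.image_width
        mirror_boxes = [
            DetectionBox(w - b.x2, b.y1, w - b.x1, b.y2, b.tooth_class, b.confidence)
            for b in layout.boxes
        ]
        mirrored = DentitionLayout(Modality.PANO, w, layout.image_height, mirror_boxes)
        mresult = number_panoramic(mirrored)
        swap = {1: 2, 2: 1, 3: 4, 4: 3}
        expected = sorted(
            FDICode(swap[a.code.quadrant], a.code.position) for a in result.assignments
        )
        assert sorted(a.code for a in mresult.assignments) == expected

    def test_rejects_non_panoramic_modality(self):
        layout = DentitionLayout(Modality.PA, 640, 640, [box(100, 100), box(200, 400)])
        with pytest.raises(WrongModalityError):
            number_panoramic(layout)


class TestSequentialNumbering:
    def test_pa_orders_left_to_right(self):
        layout = DentitionLayout(
            Modality.PA, 640, 640, [box(100, 300), box(50, 310), box(200, 305)]
        )
        assert [(b.cx, i) for b, i in number_sequential(layout)] == [(50, 1), (100, 2), (200, 3)]

    def test_bw_orders_upper_row_first_then_lower(self):
        layout = DentitionLayout(
            Modality.BW,
            640,
            640,
            [box(200, 400), box(100, 405), box(200, 150), box(100, 145)],
        )
        seq = number_sequential(layout)
        assert [(b.cx, b.cy < 300, i) for b, i in seq] == [
            (100, True, 1),
            (200, True, 2),
            (100, False, 3),
            (200, False, 4),
        ]

    def test_single_box_gets_index_1(self):
        layout = DentitionLayout(Modality.PA, 640, 640, [box(300, 300)])
        assert number_sequential(layout)[0][1] == 1

    def test_pano_is_the_wrong_mode(self):
        layout = DentitionLayout(Modality.PANO, 640, 640, [box(100, 100)])
        with pytest.raises(WrongModalityError):
            number_sequential(layout)


class TestPresenceTable:
    def test_empty_assignments_give_52_zeros(self):
        table = presence_from_assignments([])
        assert len(table) == 52 and set(table.values()) == {0}

    def test_full_permanent_dentition_gives_32_ones_20_zeros(self):
        layout, _ = generate_layout(ArchSpec())
        result = number_panoramic(layout)
        values = list(result.presence.values())
        assert values.count(1) == 32 and values.count(0) == 20
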