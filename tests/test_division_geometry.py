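"""Layers, orientation calls, packets and trichome flags."""

import numpy as np
import pytest

from prothallus.division_geometry import (
    DivisionEvent,
    MarginPolyline,
    Packet,
    assign_layers,
    classify_orientation,
    classify_packet_division,
    detect_packets,
    extract_margin,
    flag_trichomes,
    layer_update_exclusions,
)
from prothallus.images import LabelMap


def grid_labelmap(rows, cols, cell=10, ps=1.0):
    """rows x cols grid of square cells labelled 1..rows*cols."""
    labels = np.zeros((rows * cell + 4, cols * cell + 4), dtype=np.int32)
    k = 1
    for i in range(rows):
        for j in range(cols):
            labels[2 + i * cell:2 + (i + 1) * cell,
                   2 + j * cell:2 + (j + 1) * cell] = k
            k += 1
    return LabelMap(labels, pixel_size=ps)


def straight_margin(length=100.0, n=101, depth=-100.0):
    """A wide reference margin whose top edge (tangent = +x) is the nearest
    stretch for points placed just below y = 0."""
    xs = np.linspace(0, length, n)
    pts = np.column_stack([xs, np.zeros(n)])
    ring = np.vstack([pts, np.column_stack([xs[::-1], np.full(n, depth)])])
    return MarginPolyline.from_ring(ring, smooth=5)


class TestExtractMargin:
    def test_single_square_margin(self):
        lm = grid_labelmap(1, 1, cell=20)
        margin = extract_margin(lm)
        x0, x1 = margin.points[:, 0].min(), margin.points[:, 0].max()
        y0, y1 = margin.points[:, 1].min(), margin.points[:, 1].max()
        assert x1 - x0 == pytest.approx(20.0, abs=1.5)
        assert y1 - y0 == pytest.approx(20.0, abs=1.5)

    def test_trichome_excluded_from_margin(self):
        labels = np.zeros((30, 46), dtype=np.int32)
        labels[5:25, 5:25] = 1
        labels[12:18, 25:43] = 2  # protrusion sticking out to the right
        lm = LabelMap(labels, 1.0)
        margin = extract_margin(lm, {2: True})
        assert margin.points[:, 0].max() < 27.0

    def test_tangents_unit_length(self, rendered_snapshot):
        _, truth, _, _ = rendered_snapshot
        margin = extract_margin(truth)
        np.testing.assert_allclose(
            np.linalg.norm(margin.tangents, axis=1), 1.0, atol=1e-9
        )


class TestAssignLayers:
    def test_single_file_filament_is_all_marginal(self):
        lm = grid_labelmap(1, 5)
        layers = assign_layers(lm)
        assert set(layers.values()) == {"marginal"}

    def test_three_by_five_grid_has_no_inner(self):
        lm = grid_labelmap(3, 5)
        layers = assign_layers(lm)
        marginal = [l for l, v in layers.items() if v == "marginal"]
        submarginal = [l for l, v in layers.items() if v == "submarginal"]
        assert len(marginal) == 12  # outer ring
        assert len(submarginal) == 3  # enclosed middle row
        assert "inner" not in layers.values()

    def test_five_by_five_grid_has_inner_centre(self):
        lm = grid_labelmap(5, 5)
        layers = assign_layers(lm)
        assert layers[13] == "inner"  # centre cell of a 5x5 grid

    def test_layer_partition_excludes_trichomes(self):
        lm = grid_labelmap(3, 5)
        layers = assign_layers(lm, trichome_flags={1: True})
        assert layers[1] == "trichome"
        assert set(layers.values()) <= {"marginal", "submarginal", "inner",
                                        "trichome"}

    def test_exclusion_demotes_submarginal(self):
        lm = grid_labelmap(3, 5)
        layers = assign_layers(lm, exclude_submarginal={7})
        assert layers[7] == "inner"

    def test_submarginal_periclinal_daughter_excluded_next_window(self):
        # a submarginal parent divided periclinally; its inward daughter
        # must be demoted from the submarginal layer next window
        margin = straight_margin()
        events = [
            DivisionEvent(parent_id=5, daughter_ids=(50, 51), new_wall=None,
                          orientation="periclinal")
        ]
        layers_before = {5: "submarginal"}
        cents = {50: np.array([10.0, -12.0]), 51: np.array([10.0, -20.0])}
        excl = layer_update_exclusions(events, layers_before, margin, cents)
        assert excl == {51}  # the daughter farther from the margin


class TestClassifyOrientation:
    margin = None

    def setup_method(self):
        self.margin = straight_margin()

    def event_with_wall(self, angle_deg):
        a = np.deg2rad(angle_deg)
        d = np.array([np.cos(a), np.sin(a)])
        pts = np.array([50.0, -10.0]) + np.linspace(-5, 5, 11)[:, None] * d
        return DivisionEvent(parent_id=1, daughter_ids=(2, 3), new_wall=pts)

    @pytest.mark.parametrize(
        "angle,expected",
        [(0.0, "periclinal"), (90.0, "anticlinal"), (45.0, "oblique"),
         (15.0, "periclinal"), (75.0, "anticlinal")],
    )
    def test_angle_bands(self, angle, expected):
        ev = classify_orientation(
            self.event_with_wall(angle), self.margin, (50.0, -10.0)
        )
        assert ev.orientation == expected
        assert ev.wall_margin_angle == pytest.approx(angle, abs=2.0)

    def test_degenerate_wall_flagged(self):
        ev = DivisionEvent(parent_id=1, daughter_ids=(2, 3),
                           new_wall=np.array([[1.0, 1.0]]))
        out = classify_orientation(ev, self.margin, (50.0, -10.0))
        assert out.orientation == "unassigned"
        assert "degenerate_wall" in out.qc_flags

    def test_widening_oblique_band_never_flips_a_to_p(self):
        # threshold monotonicity: a wider oblique band may only move calls
        # into 'oblique', never across to the other pole
        for angle in np.linspace(0, 90, 19):
            ev_narrow = classify_orientation(
                self.event_with_wall(angle), self.margin, (50.0, -10.0),
                anticlinal_min_deg=60, periclinal_max_deg=30,
            )
            ev_wide = classify_orientation(
                self.event_with_wall(angle), self.margin, (50.0, -10.0),
                anticlinal_min_deg=70, periclinal_max_deg=20,
            )
            if ev_narrow.orientation == "anticlinal":
                assert ev_wide.orientation in ("anticlinal", "oblique")
            if ev_narrow.orientation == "periclinal":
                assert ev_wide.orientation in ("periclinal", "oblique")


class TestDetectPackets:
    def packet_map(self):
        """Two 10x20 upper cells over one 20x8 lower cell."""
        labels = np.zeros((34, 26), dtype=np.int32)
        labels[2:22, 3:13] = 1
        labels[2:22, 13:23] = 2
        labels[22:30, 3:23] = 3
        return LabelMap(labels, pixel_size=1.0)

    def test_constructed_arrangement_is_one_packet(self):
        lm = self.packet_map()
        layers = {1: "marginal", 2: "marginal", 3: "submarginal"}
        packets = detect_packets(lm, layers)
        assert len(packets) == 1
        assert packets[0].member_ids == (1, 2, 3)

    def test_wedge_fails_rectangularity(self):
        labels = np.zeros((34, 30), dtype=np.int32)
        for i in range(20):  # triangular 'wedge' cell
            labels[2 + i, 4:4 + max(1, i)] = 1
        labels[2:22, 14:24] = 2
        labels[22:30, 4:24] = 3
        lm = LabelMap(labels, 1.0)
        layers = {1: "marginal", 2: "marginal", 3: "submarginal"}
        assert detect_packets(lm, layers) == []

    def test_packets_are_disjoint(self, rendered_snapshot):
        img, truth, _, _ = rendered_snapshot
        layers = assign_layers(truth)
        packets = detect_packets(truth, layers)
        seen = set()
        for p in packets:
            assert not (seen & set(p.member_ids))
            seen |= set(p.member_ids)


class TestClassifyPacketDivision:
    packet = Packet(1, 2, 3)

    def ev(self, parent, orientation):
        return DivisionEvent(parent_id=parent, daughter_ids=(10, 11),
                             new_wall=None, orientation=orientation)

    def test_single_upper_anticlinal_is_type_I(self):
        rec = classify_packet_division(self.packet, [self.ev(1, "anticlinal")])
        assert rec.division_types == ("I",)
        assert not rec.is_complex

    def test_cluster_of_six_pattern(self):
        events = [self.ev(1, "periclinal"), self.ev(2, "periclinal"),
                  self.ev(3, "anticlinal")]
        rec = classify_packet_division(self.packet, events)
        assert rec.division_types == ("II", "II", "III")

    def test_double_division_is_complex(self):
        events = [self.ev(1, "anticlinal"), self.ev(1, "periclinal")]
        rec = classify_packet_division(self.packet, events)
        assert rec.is_complex
        assert rec.division_types == ()

    def test_quiescent_packet_is_none(self):
        rec = classify_packet_division(self.packet, [])
        assert rec.status == "none"


class TestFlagTrichomes:
    def test_no_protrusion_no_flags(self):
        lm = grid_labelmap(2, 3)
        flags = flag_trichomes(lm)
        assert not any(flags.values())

    def test_truth_mode_passthrough(self):
        lm = grid_labelmap(2, 3)
        flags = flag_trichomes(lm, truth_flags={1: True, 4: True})
        assert flags[1] and flags[4]
        assert not flags[2]

    def test_rule_based_flags_constructed_protrusion(self):
        """A thin protruding cell on an otherwise compact tissue is flagged
        by the geometric rule; the body cells are not."""
        labels = np.zeros((80, 80), dtype=np.int32)
        k = 1
        for i in range(3):
            for j in range(3):
                labels[14 + i * 20:14 + (i + 1) * 20,
                       10 + j * 20:10 + (j + 1) * 20] = k
                k += 1
        # thin spike protruding upward from the top-middle cell
        for i in range(12):
            w = max(1, 5 - i // 3)
            labels[13 - i, 40 - w:40 + w] = 10
        lm = LabelMap(labels, pixel_size=1.0)
        flags = flag_trichomes(lm)
        assert flags[10] is True
        assert not any(flags[c] for c in range(1, 10))
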