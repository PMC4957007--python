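"""Gap bridging, crossing resolution and reconstruction bookkeeping."""

import numpy as np
import pytest

from acqua.curves import fit_spline
from acqua.errors import ValidationError
from acqua.reconnect import (ReconnectionRecord, ReconnectParams, candidate_joins,
                             count_break_events, reconstruction_rate, resolve_joins)

UM = 0.32


def segment(r0, c0, r1, c1, n=40, end_kinds=("free", "free")):
    pts = np.stack([np.linspace(r0, r1, n), np.linspace(c0, c1, n)], axis=1)
    curve = fit_spline(pts, um_per_px=UM, end_kinds=end_kinds)
    curve.mean_width_um = 4.0
    return curve


class TestCandidateJoins:
    def test_collinear_segments_with_small_gap(self):
        a = segment(50, 0, 50, 100)
        b = segment(50, 105, 50, 200)  # 5 px = 1.6 um gap
        cands = candidate_joins([a, b])
        assert len(cands) == 1
        c = cands[0]
        assert c.gap_um == pytest.approx(5 * UM, abs=0.01)
        assert c.angle_deg < 1.0

    def test_perpendicular_distant_segments_rejected(self):
        a = segment(50, 0, 50, 100)
        b = segment(120, 300, 220, 300)
        assert candidate_joins([a, b]) == []

    def test_misaligned_segments_fail_angle_gate(self):
        a = segment(50, 0, 50, 100)
        b = segment(55, 110, 150, 115)  # nearly perpendicular, close
        assert candidate_joins([a, b]) == []

    def test_width_ratio_gate(self):
        a = segment(50, 0, 50, 100)
        b = segment(50, 105, 50, 200)
        b.mean_width_um = 12.0  # ratio 3 > 1.8
        assert candidate_joins([a, b]) == []

    def test_straight_through_beats_bent_pairing_at_cross(self):
        j = (100.0, 100.0)
        north = segment(40, 100, *j, end_kinds=("free", "junction"))
        south = segment(160, 100, *j, end_kinds=("free", "junction"))
        east = segment(100, 160, *j, end_kinds=("free", "junction"))
        west = segment(100, 40, *j, end_kinds=("free", "junction"))
        params = ReconnectParams(max_angle_deg=120.0)  # admit bent pairs to compare costs
        cands = candidate_joins([north, south, east, west], params)
        by_pair = {frozenset((c.curve_a, c.curve_b)): c.cost for c in cands}
        straight = [by_pair[frozenset((0, 1))], by_pair[frozenset((2, 3))]]
        bent = [v for k, v in by_pair.items() if k not in
                (frozenset((0, 1)), frozenset((2, 3)))]
        assert max(straight) < min(bent)


class TestResolveJoins:
    def test_three_collinear_fragments_chain_merge(self):
        frags = [segment(50, 0, 50, 80), segment(50, 90, 50, 170),
                 segment(50, 180, 50, 260)]
        merged, record = resolve_joins(frags)
        assert len(merged) == 1
        assert record.n_joined == 2
        assert record.n_break_events == 2
        assert merged[0].arc_length_px == pytest.approx(260.0, rel=0.01)

    def test_x_cross_resolves_to_two_filaments(self):
        j = (100.0, 100.0)
        branches = [
            segment(40, 100, *j, end_kinds=("free", "junction")),
            segment(160, 100, *j, end_kinds=("free", "junction")),
            segment(100, 160, *j, end_kinds=("free", "junction")),
            segment(100, 40, *j, end_kinds=("free", "junction")),
        ]
        merged, record = resolve_joins(branches)
        assert len(merged) == 2
        assert record.n_joined == 2

    def test_identity_when_nothing_to_join(self):
        far = [segment(50, 0, 50, 100), segment(300, 0, 300, 100)]
        merged, record = resolve_joins(far)
        assert len(merged) == 2 and record.n_joined == 0

    def test_join_does_not_lose_length(self):
        a = segment(50, 0, 50, 100)
        b = segment(50, 110, 50, 210)
        merged, _ = resolve_joins([a, b])
        assert merged[0].arc_length_px >= max(a.arc_length_px, b.arc_length_px)
        assert merged[0].arc_length_px >= (a.arc_length_px + b.arc_length_px) * 0.99

    def test_deterministic(self):
        frags = [segment(50, 0, 50, 80), segment(50, 90, 50, 170),
                 segment(52, 182, 50, 260), segment(120, 0, 120, 90)]
        out1 = resolve_joins(frags)[1]
        out2 = resolve_joins([segment(50, 0, 50, 80), segment(50, 90, 50, 170),
                              segment(52, 182, 50, 260), segment(120, 0, 120, 90)])[1]
        assert [(p.curve_a, p.curve_b, p.end_a, p.end_b) for p in out1.pairs] == \
               [(p.curve_a, p.curve_b, p.end_a, p.end_b) for p in out2.pairs]

    def test_record_invariant(self):
        frags = [segment(50, 0, 50, 80), segment(50, 90, 50, 170)]
        _, record = resolve_joins(frags)
        assert record.n_joined <= record.n_break_events


class TestEventCounting:
    def test_no_events_for_distant_curves(self):
        far = [segment(50, 0, 50, 100), segment(300, 0, 300, 100)]
        assert count_break_events(far) == 0

    def test_one_event_per_gap(self):
        frags = [segment(50, 0, 50, 80), segment(50, 90, 50, 170)]
        assert count_break_events(frags) == 1

    def test_interior_junction_segments_excluded(self):
        mid = segment(100, 95, 100, 105, end_kinds=("junction", "junction"))
        left = segment(100, 0, 100, 94, end_kinds=("free", "junction"))
        right = segment(100, 106, 100, 200, end_kinds=("free", "junction"))
        assert count_break_events([left, right, mid]) == 1


class TestReconstructionRate:
    def test_pooled_arithmetic(self):
        records = [ReconnectionRecord(2, 2), ReconnectionRecord(2, 2),
                   ReconnectionRecord(2, 4)]
        assert reconstruction_rate(records) == pytest.approx(75.0)

    def test_no_events_is_missing_not_zero(self):
        assert np.isnan(reconstruction_rate([ReconnectionRecord(0, 0)]))

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError):
            reconstruction_rate([])
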