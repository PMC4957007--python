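"""Reconnection of fragmented filaments.

Filaments arrive at this stage in pieces for two reasons: occlusion by debris
interrupts them (separate objects with a short gap), and crossings split them
at skeleton junctions (branches sharing a junction point).  Both cases reduce
to the same endpoint-pairing problem: find pairs of curve ends that are close,
mutually aligned with each other's outward tangents, and of similar width,
and merge them — greedily in increasing cost order, each endpoint used at most
once, with merged curves re-entering the pool.

The bookkeeping mirrors the per-FOV "reconstructed filaments" tally: a *break
event* is an endpoint pair matched under the distance gate alone (junction
branch ends all lie within that gate, so crossings are covered automatically),
and the joined/events ratio pooled over FOVs is the reconstruction rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from acqua.curves import FilamentCurve, endpoint_geometry, fit_spline
from acqua.errors import ValidationError


@dataclass
class JoinCandidate:
    curve_a: int
    curve_b: int
    end_a: int           # 0 = curve start, 1 = curve end
    end_b: int
    gap_um: float
    angle_a_deg: float   # end_a outward tangent vs direction toward end_b
    angle_b_deg: float
    cost: float

    @property
    def angle_deg(self) -> float:
        return 0.5 * (self.angle_a_deg + self.angle_b_deg)


@dataclass
class ReconnectionRecord:
    n_joined: int = 0
    n_break_events: int = 0
    pairs: list = field(default_factory=list)


@dataclass
class ReconnectParams:
    max_gap_um: float = 15.0
    max_angle_deg: float = 30.0
    width_ratio_max: float = 1.8

    def __post_init__(self):
        if self.max_gap_um <= 0 or self.max_angle_deg <= 0 or self.width_ratio_max < 1:
            raise ValidationError("invalid reconnection parameters")


def _end_geometry(curve: FilamentCurve):
    g = endpoint_geometry(curve)
    return [(g[0][0], g[0][1]), (g[1][0], g[1][1])]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    cosv = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosv))


def _pair_geometry(ga, gb, um_per_px: float, junction_pair: bool = False):
    """Gap (μm) and the two alignment angles for an endpoint pair.

    Ordinarily each end's outward tangent is compared with the direction
    toward the partner end.  For coincident endpoints, and for pairs of
    junction-born ends (skeleton geometry inside a junction zone is distorted,
    so the short baseline between the ends points nowhere meaningful),
    alignment is judged by the tangents alone: a straight-through pair has
    opposed outward tangents (angle 0 by this measure), a right-angle branch
    pair scores 90°.
    """
    pos_a, tan_a = ga
    pos_b, tan_b = gb
    delta = pos_b - pos_a
    gap_px = float(np.hypot(*delta))
    gap_um = gap_px * um_per_px
    if junction_pair or gap_px < 1e-6:
        ang = _angle_deg(tan_a, -tan_b)
        return gap_um, ang, ang
    return gap_um, _angle_deg(tan_a, delta), _angle_deg(tan_b, -delta)


def candidate_joins(curves: list[FilamentCurve], params: ReconnectParams | None = None,
                    um_per_px: float | None = None) -> list[JoinCandidate]:
    """All endpoint pairs passing the gap, alignment and width gates.

    Cost = gap/max_gap + (angle_a + angle_b)/(2·max_angle) + |log width ratio|,
    sorted ascending with a deterministic tie-break on (curve, endpoint) ids.
    """
    p = params or ReconnectParams()
    if not curves:
        return []
    upp = um_per_px if um_per_px is not None else curves[0].um_per_px
    geoms = [_end_geometry(c) for c in curves]
    cands: list[JoinCandidate] = []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            for ea in (0, 1):
                for eb in (0, 1):
                    jpair = (curves[i].end_kinds[ea] == "junction"
                             and curves[j].end_kinds[eb] == "junction")
                    gap_um, ang_a, ang_b = _pair_geometry(
                        geoms[i][ea], geoms[j][eb], upp, junction_pair=jpair)
                    if gap_um > p.max_gap_um:
                        continue
                    if ang_a > p.max_angle_deg or ang_b > p.max_angle_deg:
                        continue
                    wa, wb = curves[i].mean_width_um, curves[j].mean_width_um
                    if np.isfinite(wa) and np.isfinite(wb) and min(wa, wb) > 0:
                        ratio = max(wa, wb) / min(wa, wb)
                    else:
                        ratio = 1.0
                    if ratio > p.width_ratio_max:
                        continue
                    cost = (gap_um / p.max_gap_um
                            + (ang_a + ang_b) / (2.0 * p.max_angle_deg)
                            + abs(math.log(ratio)))
                    cands.append(JoinCandidate(i, j, ea, eb, gap_um, ang_a, ang_b, cost))
    cands.sort(key=lambda c: (c.cost, c.curve_a, c.curve_b, c.end_a, c.end_b))
    return cands


def count_break_events(curves: list[FilamentCurve], params: ReconnectParams | None = None,
                       um_per_px: float | None = None) -> int:
    """Break/cross events: greedy endpoint matching under the distance gate alone.

    Each matched pair is one event eligible for joining — a gap between two
    fragments, or one branch pairing at a junction (a 4-branch crossing yields
    two events).  Angle and width gates are deliberately ignored here: they are
    what can make a join *fail*, not what makes the event exist.
    """
    p = params or ReconnectParams()
    if not curves:
        return 0
    upp = um_per_px if um_per_px is not None else curves[0].um_per_px
    geoms = [_end_geometry(c) for c in curves]
    # interior junction-to-junction segments are decomposition artifacts, not
    # break ends: their endpoints do not constitute events
    interior = [c.end_kinds == ("junction", "junction") for c in curves]
    pairs = []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            if interior[i] or interior[j]:
                continue
            for ea in (0, 1):
                for eb in (0, 1):
                    gap_um, _, _ = _pair_geometry(geoms[i][ea], geoms[j][eb], upp)
                    if gap_um <= p.max_gap_um:
                        pairs.append((gap_um, i, j, ea, eb))
    pairs.sort()
    used: set = set()
    events = 0
    for _, i, j, ea, eb in pairs:
        if (i, ea) in used or (j, eb) in used:
            continue
        used.add((i, ea))
        used.add((j, eb))
        events += 1
    return events


def _merge(curve_a: FilamentCurve, end_a: int, curve_b: FilamentCurve, end_b: int,
           smoothing: float | None = None) -> FilamentCurve:
    """Refit one spline over the union of the two point paths, bridged across the gap."""
    pts_a = curve_a.points if end_a == 1 else curve_a.points[::-1]
    pts_b = curve_b.points if end_b == 0 else curve_b.points[::-1]
    pts = np.vstack([pts_a, pts_b])
    outer_kinds = (curve_a.end_kinds[1 - end_a], curve_b.end_kinds[1 - end_b])
    merged = fit_spline(pts, smoothing=smoothing, um_per_px=curve_a.um_per_px,
                        source_ids=tuple(curve_a.source_ids) + tuple(curve_b.source_ids),
                        end_kinds=outer_kinds)
    wa, wb = curve_a.mean_width_um, curve_b.mean_width_um
    la, lb = curve_a.arc_length_px, curve_b.arc_length_px
    if np.isfinite(wa) and np.isfinite(wb) and (la + lb) > 0:
        merged.mean_width_um = (wa * la + wb * lb) / (la + lb)
    return merged


def resolve_joins(curves: list[FilamentCurve], params: ReconnectParams | None = None,
                  smoothing: float | None = None) -> tuple[list[FilamentCurve], ReconnectionRecord]:
    """Greedy cost-ordered merging of join candidates.

    The cheapest candidate is accepted, the two fragments are merged (spline
    refit over the union of their points) and the merged curve re-enters the
    pool with fresh endpoint geometry; candidates are then recomputed.  Each
    endpoint is consumed by at most one join.  Self-joins (a curve meeting
    itself) are rejected.
    """
    p = params or ReconnectParams()
    record = ReconnectionRecord(n_break_events=count_break_events(curves, p))
    pool = list(curves)
    while True:
        cands = candidate_joins(pool, p)
        if not cands:
            break
        best = cands[0]
        a, b = pool[best.curve_a], pool[best.curve_b]
        merged = _merge(a, best.end_a, b, best.end_b, smoothing=smoothing)
        pool = [c for k, c in enumerate(pool) if k not in (best.curve_a, best.curve_b)]
        pool.append(merged)
        record.n_joined += 1
        record.pairs.append(best)
    record.n_break_events = max(record.n_break_events, record.n_joined)
    return pool, record


def reconstruction_rate(records: list[ReconnectionRecord]) -> float:
    """Pooled percent of break/cross events successfully joined.

    NaN (missing), not 0, when no events occurred at all.
    """
    if not records:
        raise ValidationError("no reconnection records")
    joined = sum(r.n_joined for r in records)
    events = sum(r.n_break_events for r in records)
    if events == 0:
        return float("nan")
    return 100.0 * joined / events
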