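"""Per-field-of-view morphometric reporting.

Assembles the automated analogue of one validation-table row: filament-of-
interest count, total length (μm), reconnection tally, filamentous-object
count and the percentage of object area held by filaments of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from acqua.curves import FilamentCurve
from acqua.errors import ConfigError
from acqua.reconnect import ReconnectionRecord
from acqua.segment import LabeledObjects, area_fractions

CSV_HEADER = "image_id,a_count,a_tl_um,rec_joined,rec_events,fil_obj,afil_aobj_pct"


@dataclass
class Calibration:
    """Spatial calibration of the optical setup (10× bright-field default)."""

    um_per_px: float = 0.32
    fov_width_px: int = 5184
    fov_height_px: int = 3456

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ConfigError("um_per_px must be positive")


@dataclass
class FilamentRow:
    length_um: float
    width_um: float
    touches_border: bool = False


@dataclass
class FOVReport:
    image_id: str
    a_count: int
    a_tl_um: float
    rec_joined: int
    rec_events: int
    n_filamentous_objects: int
    afil_aobj_pct: float
    filaments: list[FilamentRow] = field(default_factory=list)

    def to_csv_row(self) -> str:
        """One validation-table row; lengths rounded to integer μm, as printed tables do."""
        af = "" if np.isnan(self.afil_aobj_pct) else f"{self.afil_aobj_pct:.1f}"
        return (f"{self.image_id},{self.a_count},{round(self.a_tl_um)},"
                f"{self.rec_joined},{self.rec_events},{self.n_filamentous_objects},{af}")

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "a_count": self.a_count,
            "a_tl_um": self.a_tl_um,
            "rec_joined": self.rec_joined,
            "rec_events": self.rec_events,
            "fil_obj": self.n_filamentous_objects,
            "afil_aobj_pct": self.afil_aobj_pct,
            "filaments": [vars(f) for f in self.filaments],
        }


def classify_curves(curves: list[FilamentCurve], min_length_um: float = 50.0,
                    width_range_um: tuple[float, float] = (2.0, 12.0),
                    min_elongation: float = 5.0) -> list[FilamentCurve]:
    """Flag final (post-reconnection) curves as filaments of interest.

    A curve qualifies when its arc length reaches ``min_length_um``, its mean
    width lies in ``width_range_um`` (curves with unknown width pass this
    gate), and its length/width elongation reaches ``min_elongation``.
    """
    lo_w, hi_w = width_range_um
    for c in curves:
        ok = c.arc_length_um >= min_length_um
        if np.isfinite(c.mean_width_um):
            ok = ok and lo_w <= c.mean_width_um <= hi_w
            ok = ok and c.arc_length_um / max(c.mean_width_um, 1e-9) >= min_elongation
        c.is_of_interest = ok
    return curves


def measure_fov(curves: list[FilamentCurve], objects: LabeledObjects,
                record: ReconnectionRecord, calib: Calibration,
                image_id: str = "") -> FOVReport:
    """Assemble the per-FOV report from classified curves and objects.

    Only curves flagged of-interest contribute to the count and total length;
    the filamentous-object count and area fraction come from the object-level
    classification (they describe the scene, including filamentous noise).
    """
    if calib is None:
        raise ConfigError("calibration is required")
    interest = [c for c in curves if c.is_of_interest]
    border_labels = {o.label for o in objects.objects if o.touches_border}
    rows = [FilamentRow(
        length_um=c.arc_length_px * calib.um_per_px,
        width_um=c.mean_width_um,
        touches_border=bool(set(c.source_ids) & border_labels),
    ) for c in interest]
    fracs = area_fractions(objects) if objects.objects else {"filament_area_fraction": float("nan")}
    return FOVReport(
        image_id=image_id,
        a_count=len(rows),
        a_tl_um=float(sum(r.length_um for r in rows)),
        rec_joined=record.n_joined,
        rec_events=record.n_break_events,
        n_filamentous_objects=sum(1 for o in objects.objects if o.is_filamentous),
        afil_aobj_pct=fracs["filament_area_fraction"],
        filaments=rows,
    )


def fov_area_mm2(calib: Calibration) -> float:
    """Field-of-view area in mm² from the calibration (width·height·μm²/px²)."""
    return calib.fov_width_px * calib.fov_height_px * calib.um_per_px**2 / 1e6
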