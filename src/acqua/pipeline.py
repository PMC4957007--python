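"""End-to-end processing: image → per-FOV report.

``process_image`` chains the stages — Sobel gradient magnitude, thresholding
and object classification, skeleton-graph tracing, spline fitting, fragment
reconnection, and reporting — under one configuration object that serializes
to/from YAML.  ``batch`` maps it over a directory, producing one CSV row per
image in stable filename order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from acqua._version import __version__ as _pkg_version
from acqua.curves import fit_spline, width_profile
from acqua.errors import AcquaError, ConfigError
from acqua.io import read_image
from acqua.measure import Calibration, FOVReport, classify_curves, measure_fov
from acqua.preprocess import normalize_gradient, sobel_magnitude
from acqua.reconnect import ReconnectParams, resolve_joins
from acqua.segment import binarize, classify_objects, compute_features, label_objects
from acqua.trace import (build_graph, edge_end_kinds, path_length_px, skeletonize,
                         split_at_junctions)

log = logging.getLogger("acqua")


@dataclass
class PipelineConfig:
    """All tunable parameters of the processing chain.

    ``smooth_sigma`` optionally Gaussian-smooths the gradient magnitude before
    thresholding (0 disables); ``edge_width_correction_px`` compensates the
    systematic dilation of gradient-magnitude objects by the Sobel support
    (about one pixel per side) when reporting filament widths.
    """

    um_per_px: float = 0.32
    # preprocessing / binarization
    border_trim_px: int = 3        # zero-padding makes the frame edge fire; discard it
    smooth_sigma: float = 1.0
    binarize_method: str = "otsu"
    binarize_threshold: float | None = None
    # absolute gradient floor (intensity units): Otsu normalizes per image, so a
    # scene with no real edges would otherwise promote sensor noise to foreground
    min_gradient: float = 0.15
    # object extraction
    min_object_area: int = 30
    closing_radius: int = 2
    # object classification
    min_elongation: float = 5.0
    min_length_um: float = 50.0
    width_range_um: tuple[float, float] = (2.0, 12.0)
    # tracing / splines
    prune_px: float = 8.0
    spline_smoothing: float | None = None   # None = per-path default budget
    min_curve_px: float = 6.0
    curve_min_elongation: float = 2.5       # admission gate into the reconnection pool
    edge_width_correction_px: float = 2.0
    # reconnection
    max_gap_um: float = 15.0
    max_angle_deg: float = 30.0
    width_ratio_max: float = 1.8

    def reconnect_params(self) -> ReconnectParams:
        return ReconnectParams(self.max_gap_um, self.max_angle_deg, self.width_ratio_max)

    def calibration(self) -> Calibration:
        return Calibration(um_per_px=self.um_per_px)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "width_range_um" in raw:
            raw["width_range_um"] = tuple(raw["width_range_um"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def process_array(image: np.ndarray, config: PipelineConfig | None = None,
                  image_id: str = "") -> FOVReport:
    """Run the full chain on an in-memory [0, 1] gray image."""
    cfg = config or PipelineConfig()
    grad = sobel_magnitude(image)
    H = grad["H"]
    b = cfg.border_trim_px
    if b > 0:
        H = H.copy()
        H[:b, :] = H[-b:, :] = 0.0
        H[:, :b] = H[:, -b:] = 0.0
    H_raw = H
    H = normalize_gradient(H)
    if cfg.smooth_sigma > 0:
        H = normalize_gradient(ndimage.gaussian_filter(H, cfg.smooth_sigma))
    mask = binarize(H, method=cfg.binarize_method, threshold=cfg.binarize_threshold)
    if cfg.min_gradient > 0:
        mask &= ndimage.gaussian_filter(H_raw, max(cfg.smooth_sigma, 0.5)) >= cfg.min_gradient
    objs = label_objects(mask, min_object_area=cfg.min_object_area,
                         closing_radius=cfg.closing_radius)
    compute_features(objs)
    classify_objects(objs, min_elongation=cfg.min_elongation,
                     min_length_um=cfg.min_length_um,
                     width_range_um=cfg.width_range_um, um_per_px=cfg.um_per_px)

    foreground = objs.label_map > 0
    curves = []
    for obj in objs.objects:
        if obj.elongation < cfg.curve_min_elongation:
            continue
        skel = skeletonize(objs.mask_for(obj.label))
        graph = build_graph(skel, prune_px=cfg.prune_px)
        kinds = edge_end_kinds(graph)
        for path, (kind_a, kind_b) in zip(split_at_junctions(graph), kinds):
            if path_length_px(path) < cfg.min_curve_px:
                continue
            curve = fit_spline(path, smoothing=cfg.spline_smoothing,
                               um_per_px=cfg.um_per_px, source_ids=(obj.label,),
                               end_kinds=(
                                   "junction" if kind_a == "junction" else "free",
                                   "junction" if kind_b == "junction" else "free"))
            width_profile(curve, foreground)
            curve.mean_width_um = max(
                curve.mean_width_um - cfg.edge_width_correction_px * cfg.um_per_px, 0.0)
            curves.append(curve)

    merged, record = resolve_joins(curves, cfg.reconnect_params(),
                                   smoothing=cfg.spline_smoothing)
    classify_curves(merged, min_length_um=cfg.min_length_um,
                    width_range_um=cfg.width_range_um,
                    min_elongation=cfg.min_elongation)
    return measure_fov(merged, objs, record, cfg.calibration(), image_id=image_id)


def process_image(path, config: PipelineConfig | None = None) -> FOVReport:
    """Run the full chain on an image file (TIFF/PNG)."""
    p = Path(path)
    return process_array(read_image(p), config, image_id=p.stem)


def report_json(report: FOVReport, config: PipelineConfig) -> str:
    """Serialize a report with provenance (config hash, package version)."""
    payload = report.to_dict()
    payload["provenance"] = {"config_hash": config.config_hash(),
                             "acqua_version": _pkg_version}
    return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)


def batch(directory, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Process every TIFF/PNG in a directory; one row per readable image.

    Unreadable or invalid files are logged and skipped; rows follow stable
    filename order.  An empty directory is an error.
    """
    cfg = config or PipelineConfig()
    d = Path(directory)
    files = sorted(p for p in d.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff", ".png")) if d.is_dir() else []
    if not files:
        raise ConfigError(f"no images found in {directory}")
    rows = []
    for p in files:
        try:
            rep = process_image(p, cfg)
        except AcquaError as exc:
            log.warning("skipping %s: %s", p.name, exc)
            continue
        r = rep.to_dict()
        r.pop("filaments")
        rows.append(r)
    return pd.DataFrame(rows)
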