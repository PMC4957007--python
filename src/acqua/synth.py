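"""Seeded synthetic bright-field scenes with ground truth.

The generator emulates the statistical structure of settled-phytoplankton
micrographs at 1/4 linear scale of the real field of view: dark, smoothly
curved filaments of log-normally distributed length on a bright background
with a slow intensity gradient, plus compact particle distractors ("blobs"),
optional filament crossings placed by construction, optional interruptions
(breaks with a recorded gap), and additive Gaussian sensor noise.  Every draw
comes from one seeded generator, so a scene is reproducible byte-for-byte
from its configuration.

Filament backbones follow sinusoidally modulated headings — smooth, bounded
curvature, no self-crossing curls — integrated at 1 px steps.  Widths are
constant along a filament, as trichomes of one taxon are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from acqua.errors import ValidationError


@dataclass
class SceneConfig:
    seed: int = 0
    height_px: int = 864           # 1/4-scale FOV (full frame is 3456 x 5184)
    width_px: int = 1296
    um_per_px: float = 0.32
    n_filaments: int = 10
    length_um_median: float = 130.0
    length_um_sigma: float = 0.30  # log-normal shape
    length_um_min: float = 70.0
    length_um_max: float = 300.0
    width_um_range: tuple[float, float] = (3.0, 6.0)
    wiggle_amp_rad: tuple[float, float] = (0.15, 0.55)   # heading modulation depth
    wiggle_wavelength_px: tuple[float, float] = (250.0, 700.0)
    n_crossings: int = 0
    n_breaks: int = 0
    gap_um_range: tuple[float, float] = (5.0, 12.0)
    n_blobs: int = 0
    blob_radius_px_range: tuple[float, float] = (3.0, 8.0)
    background_level: float = 0.85
    background_gradient_amplitude: float = 0.15
    filament_contrast: float = 0.30
    noise_sd: float = 0.01
    margin_px: float = 30.0
    min_separation_px: float = 6.0
    endpoint_clearance_px: float = 55.0  # keep filament ends out of the join gate of neighbors
    invert: bool = False           # True renders bright filaments on dark ground

    def __post_init__(self):
        if self.n_filaments < 0 or self.n_breaks < 0 or self.n_blobs < 0 or self.n_crossings < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_crossings > self.n_filaments:
            raise ValidationError("n_crossings cannot exceed n_filaments")
        if self.length_um_sigma < 0 or self.width_um_range[0] <= 0:
            raise ValidationError("invalid distribution parameters")


@dataclass
class FilamentTruth:
    id: int
    backbone: np.ndarray            # (n, 2) float (row, col), 1 px sample spacing
    width_um: float
    length_um: float                # pre-break backbone arc length
    fragments: list = field(default_factory=list)  # (n, 2) arrays actually rendered


@dataclass
class SceneTruth:
    config: SceneConfig
    filaments: list[FilamentTruth] = field(default_factory=list)
    blobs: list = field(default_factory=list)       # (row, col, radius_px)
    breaks: list = field(default_factory=list)      # {filament, gap_um, at_um}
    crossings: list = field(default_factory=list)   # {filament_a, filament_b, point}
    background_direction_rad: float = 0.0

    @property
    def n_filaments(self) -> int:
        return len(self.filaments)

    @property
    def total_length_um(self) -> float:
        return float(sum(f.length_um for f in self.filaments))

    def truth_area_fractions(self) -> dict[str, float]:
        """Analytic area bookkeeping: filament ribbon area vs all object area."""
        cfg = self.config
        fil = sum(f.length_um / cfg.um_per_px * (f.width_um / cfg.um_per_px)
                  for f in self.filaments)
        blob = sum(math.pi * r * r for _, _, r in self.blobs)
        total = fil + blob
        if total == 0:
            return {"filament_area_fraction": float("nan")}
        return {"filament_area_fraction": 100.0 * fil / total}


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


def _walk(start: np.ndarray, theta0: float, length_px: float, amp: float,
          wavelength: float, phase: float) -> np.ndarray:
    """Integrate a sinusoidally modulated heading at unit steps."""
    n = max(int(round(length_px)), 2)
    s = np.arange(n, dtype=float)
    theta = theta0 + amp * np.sin(2.0 * math.pi * s / wavelength + phase)
    steps = np.stack([np.sin(theta), np.cos(theta)], axis=1)  # (d_row, d_col)
    pts = start + np.concatenate([[np.zeros(2)], np.cumsum(steps[:-1], axis=0)])
    return pts


def _inside(pts: np.ndarray, cfg: SceneConfig) -> bool:
    m = cfg.margin_px
    return bool((pts[:, 0] > m).all() and (pts[:, 0] < cfg.height_px - m).all()
                and (pts[:, 1] > m).all() and (pts[:, 1] < cfg.width_px - m).all())


def generate_scene(config: SceneConfig) -> SceneTruth:
    """Draw a reproducible scene layout with full ground truth.

    Free filaments are placed by rejection sampling to keep a clearance of at
    least ``min_separation_px`` plus the ribbon half-widths between backbones;
    crossing filaments are routed through a point of an existing filament at a
    steep angle, exempt from the clearance rule near the crossing.  Raises
    after bounded retries if the frame cannot accommodate the requested count.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = SceneTruth(config=cfg, background_direction_rad=float(rng.uniform(0, 2 * math.pi)))

    placed_pts: list[np.ndarray] = []
    placed_halfw: list[np.ndarray] = []
    placed_ends: list[np.ndarray] = []
    tree: cKDTree | None = None
    end_tree: cKDTree | None = None

    def _end_region(pts: np.ndarray) -> np.ndarray:
        k = min(int(cfg.endpoint_clearance_px), len(pts))
        return np.vstack([pts[:k:4], pts[-k::4]])

    def clearance_ok(pts: np.ndarray, halfw_px: float, exempt_center=None, exempt_radius=0.0) -> bool:
        def mask_exempt(sub, bad):
            if exempt_center is None:
                return bad
            near = np.sqrt(((sub - exempt_center) ** 2).sum(axis=1)) < exempt_radius
            return bad & ~near
        if tree is not None:
            sub = pts[::4]
            d, idx = tree.query(sub)
            limit = halfw_px + np.concatenate(placed_halfw)[idx] + cfg.min_separation_px
            if mask_exempt(sub, d < limit).any():
                return False
            # this filament's ends must not fall within the join gate of any neighbor
            ends = _end_region(pts)
            d_end, _ = tree.query(ends)
            if mask_exempt(ends, d_end < cfg.endpoint_clearance_px).any():
                return False
        if end_tree is not None:
            # nor may its body run through a neighbor's end region
            sub = pts[::4]
            d2, _ = end_tree.query(sub)
            if mask_exempt(sub, d2 < cfg.endpoint_clearance_px).any():
                return False
        return True

    def register(pts: np.ndarray, halfw_px: float):
        nonlocal tree, end_tree
        placed_pts.append(pts[::4])
        placed_halfw.append(np.full(len(pts[::4]), halfw_px))
        placed_ends.append(_end_region(pts))
        tree = cKDTree(np.vstack(placed_pts))
        end_tree = cKDTree(np.vstack(placed_ends))

    def draw_length_px() -> float:
        lu = float(np.exp(rng.normal(math.log(cfg.length_um_median), cfg.length_um_sigma)))
        return float(np.clip(lu, cfg.length_um_min, cfg.length_um_max)) / cfg.um_per_px

    n_free = cfg.n_filaments - cfg.n_crossings
    fid = 0
    for _ in range(n_free):
        width_um = float(rng.uniform(*cfg.width_um_range))
        halfw_px = 0.5 * width_um / cfg.um_per_px
        ok = False
        for _attempt in range(1500):
            length_px = draw_length_px()
            start = np.array([rng.uniform(cfg.margin_px, cfg.height_px - cfg.margin_px),
                              rng.uniform(cfg.margin_px, cfg.width_px - cfg.margin_px)])
            pts = _walk(start, rng.uniform(0, 2 * math.pi), length_px,
                        rng.uniform(*cfg.wiggle_amp_rad),
                        rng.uniform(*cfg.wiggle_wavelength_px),
                        rng.uniform(0, 2 * math.pi))
            if _inside(pts, cfg) and clearance_ok(pts, halfw_px):
                ok = True
                break
        if not ok:
            raise ValidationError("infeasible packing: could not place a filament")
        truth.filaments.append(FilamentTruth(
            id=fid, backbone=pts, width_um=width_um,
            length_um=_polyline_length(pts) * cfg.um_per_px, fragments=[pts]))
        register(pts, halfw_px)
        fid += 1

    for _ in range(cfg.n_crossings):
        if not truth.filaments:
            raise ValidationError("crossings require at least one placed filament")
        width_um = float(rng.uniform(*cfg.width_um_range))
        halfw_px = 0.5 * width_um / cfg.um_per_px
        ok = False
        for _attempt in range(1500):
            host = truth.filaments[int(rng.integers(0, len(truth.filaments)))]
            k = int(rng.integers(int(0.3 * len(host.backbone)), int(0.7 * len(host.backbone))))
            anchor = host.backbone[k]
            d = host.backbone[min(k + 5, len(host.backbone) - 1)] - host.backbone[max(k - 5, 0)]
            host_theta = math.atan2(d[0], d[1])
            cross_theta = host_theta + float(rng.choice([-1.0, 1.0])) * rng.uniform(
                math.radians(55), math.radians(90))
            length_px = draw_length_px()
            u = float(rng.uniform(0.35, 0.65))     # anchor sits at fraction u of the crosser
            back = _walk(anchor, cross_theta + math.pi, u * length_px, 0.0, 1e9, 0.0)
            fwd = _walk(anchor, cross_theta, (1 - u) * length_px,
                        rng.uniform(*cfg.wiggle_amp_rad),
                        rng.uniform(*cfg.wiggle_wavelength_px),
                        rng.uniform(0, 2 * math.pi))
            pts = np.vstack([back[::-1], fwd[1:]])
            exempt_r = (halfw_px + 0.5 * host.width_um / cfg.um_per_px
                        + cfg.min_separation_px + 12.0)
            if _inside(pts, cfg) and clearance_ok(pts, halfw_px, anchor, exempt_r):
                ok = True
                break
        if not ok:
            raise ValidationError("infeasible packing: could not place a crossing filament")
        truth.filaments.append(FilamentTruth(
            id=fid, backbone=pts, width_um=width_um,
            length_um=_polyline_length(pts) * cfg.um_per_px, fragments=[pts]))
        truth.crossings.append({"filament_a": host.id, "filament_b": fid,
                                "point": tuple(anchor)})
        register(pts, halfw_px)
        fid += 1

    # breaks: cut a central interval of gap_um out of distinct filaments
    if cfg.n_breaks > 0:
        if cfg.n_breaks > len(truth.filaments):
            raise ValidationError("more breaks than filaments")
        victims = rng.choice(len(truth.filaments), size=cfg.n_breaks, replace=False)
        for v in victims:
            f = truth.filaments[int(v)]
            gap_um = float(rng.uniform(*cfg.gap_um_range))
            gap_px = gap_um / cfg.um_per_px
            n = len(f.backbone)
            cut = int(rng.uniform(0.35, 0.65) * n)   # backbone samples are 1 px apart
            half = int(round(gap_px / 2.0))
            a, b = f.backbone[:max(cut - half, 2)], f.backbone[min(cut + half, n - 2):]
            f.fragments = [a, b]
            truth.breaks.append({"filament": f.id, "gap_um": gap_um,
                                 "at_um": cut * cfg.um_per_px})

    # compact distractor particles
    for _ in range(cfg.n_blobs):
        r = float(rng.uniform(*cfg.blob_radius_px_range))
        for _attempt in range(100):
            pos = np.array([rng.uniform(cfg.margin_px, cfg.height_px - cfg.margin_px),
                            rng.uniform(cfg.margin_px, cfg.width_px - cfg.margin_px)])
            if tree is None:
                break
            d, _ = tree.query(pos)
            if d > r + cfg.min_separation_px + 14.0:
                break
        truth.blobs.append((float(pos[0]), float(pos[1]), r))

    return truth


def _stamp_ribbon(canvas: np.ndarray, pts: np.ndarray, radius_px: float) -> None:
    """Mark a constant-width ribbon around a polyline on a boolean canvas."""
    r_int = int(math.ceil(radius_px)) + 2
    r0 = max(int(pts[:, 0].min()) - r_int, 0)
    r1 = min(int(pts[:, 0].max()) + r_int + 1, canvas.shape[0])
    c0 = max(int(pts[:, 1].min()) - r_int, 0)
    c1 = min(int(pts[:, 1].max()) + r_int + 1, canvas.shape[1])
    box = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    rr = np.clip(np.round(pts[:, 0]).astype(int) - r0, 0, box.shape[0] - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int) - c0, 0, box.shape[1] - 1)
    box[rr, cc] = True
    dist = ndimage.distance_transform_edt(~box)
    canvas[r0:r1, c0:c1] |= dist <= radius_px


def render(truth: SceneTruth, config: SceneConfig | None = None) -> np.ndarray:
    """Rasterize a scene layout into a [0, 1] grayscale image.

    Filament fragments and blobs are drawn as uniformly dark material on a
    bright background with a planar intensity gradient; seeded Gaussian noise
    is added last.  ``invert=True`` flips to dark-ground contrast.
    """
    cfg = config or truth.config
    h, w = cfg.height_px, cfg.width_px
    yy, xx = np.mgrid[0:h, 0:w]
    direction = truth.background_direction_rad
    ramp = (math.sin(direction) * yy + math.cos(direction) * xx).astype(float)
    if ramp.max() > ramp.min():
        ramp = (ramp - ramp.min()) / (ramp.max() - ramp.min()) - 0.5
    img = cfg.background_level + cfg.background_gradient_amplitude * ramp

    material = np.zeros((h, w), dtype=bool)
    for f in truth.filaments:
        radius = 0.5 * f.width_um / cfg.um_per_px
        for frag in f.fragments:
            if len(frag) >= 2:
                _stamp_ribbon(material, frag, radius)
    for r, c, radius in truth.blobs:
        _stamp_ribbon(material, np.array([[r, c], [r, c + 1e-6]]), radius)

    img = np.where(material, img - cfg.filament_contrast, img)
    rng = np.random.default_rng(cfg.seed + 7919)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if cfg.invert:
        img = 1.0 - img
    return img
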