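"""Segmentation and object classification.

The gradient-magnitude image marks filament *borders*; thresholding it yields
outline rings that morphological closing and hole filling turn into solid
objects.  Objects are then scored by elongation (skeleton length over mean
width) to separate filamentous material from cells and detritus, and a second
length/width gate selects the filaments of interest among the filamentous
objects — the two-tier classification behind per-FOV object counts and area
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.morphology import closing as _sk_closing, disk, skeletonize as _sk_skeletonize

from acqua.errors import ConfigError, ValidationError


@dataclass
class ObjectFeature:
    """Morphometric features of one labeled object."""

    label: int
    area_px: int
    skeleton_length_px: float
    mean_width_px: float
    elongation: float
    touches_border: bool = False
    is_filamentous: bool = False
    is_of_interest: bool = False


@dataclass
class LabeledObjects:
    """Label raster (0 = background) plus per-object features."""

    label_map: np.ndarray
    objects: list[ObjectFeature] = field(default_factory=list)

    def mask_for(self, lbl: int) -> np.ndarray:
        return self.label_map == lbl


def binarize(gradient: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Threshold a [0, 1] gradient image into a foreground mask.

    ``method="otsu"`` picks the threshold by Otsu's between-class variance
    criterion; ``method="fixed"`` requires an explicit ``threshold``.  The mask
    is True where intensity >= threshold.
    """
    arr = np.asarray(gradient, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("gradient contains non-finite values")
    if method == "fixed":
        if threshold is None:
            raise ConfigError("method='fixed' requires a threshold")
        t = float(threshold)
    elif method == "otsu":
        if arr.min() == arr.max():
            return np.zeros_like(arr, dtype=bool)
        t = float(threshold_otsu(arr))
    else:
        raise ConfigError(f"unknown binarization method {method!r}")
    return arr >= t


def label_objects(mask: np.ndarray, min_object_area: int = 30, closing_radius: int = 1) -> LabeledObjects:
    """Close, fill, label (8-connected) and size-filter a binary mask.

    Morphological closing (disk of ``closing_radius``) bridges the double-edge
    rings produced by gradient thresholding; interior holes are filled; objects
    below ``min_object_area`` pixels are discarded and labels renumbered
    consecutively.  Features beyond area are filled in by
    :func:`compute_features`.
    """
    m = np.asarray(mask, dtype=bool)
    if closing_radius > 0:
        m = _sk_closing(m, disk(closing_radius))
    m = ndimage.binary_fill_holes(m)
    lab = _sk_label(m, connectivity=2)
    objs: list[ObjectFeature] = []
    out = np.zeros_like(lab)
    next_lbl = 0
    border = np.zeros_like(m)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for lbl in range(1, lab.max() + 1):
        sel = lab == lbl
        area = int(sel.sum())
        if area < min_object_area:
            continue
        next_lbl += 1
        out[sel] = next_lbl
        objs.append(ObjectFeature(
            label=next_lbl, area_px=area,
            skeleton_length_px=0.0, mean_width_px=0.0, elongation=0.0,
            touches_border=bool((sel & border).any()),
        ))
    return LabeledObjects(label_map=out, objects=objs)


_SQRT2 = math.sqrt(2.0)


def _skeleton_path_length(skel: np.ndarray) -> float:
    """Geometric length of a skeleton: unit steps + sqrt(2) diagonal steps.

    Counts each 8-neighbor link once (half the summed per-pixel link lengths).
    """
    s = skel.astype(bool)
    length = 0.0
    # axial links
    length += np.count_nonzero(s[:, :-1] & s[:, 1:])
    length += np.count_nonzero(s[:-1, :] & s[1:, :])
    # diagonal links, skipped when an axial detour through a shared neighbor exists
    d1 = s[:-1, :-1] & s[1:, 1:] & ~(s[:-1, 1:] | s[1:, :-1])
    d2 = s[:-1, 1:] & s[1:, :-1] & ~(s[:-1, :-1] | s[1:, 1:])
    length += _SQRT2 * (np.count_nonzero(d1) + np.count_nonzero(d2))
    return float(length)


def compute_features(objs: LabeledObjects) -> LabeledObjects:
    """Fill skeleton length, mean width and elongation for each object.

    Width is ``2·EDT − 1`` sampled on the object's skeleton (the distance
    transform on the medial axis reads half-width plus half a pixel);
    elongation is skeleton length / mean width.
    """
    dist = ndimage.distance_transform_edt(objs.label_map > 0)
    for obj in objs.objects:
        sel = objs.mask_for(obj.label)
        skel = _sk_skeletonize(sel, method="lee")
        if not skel.any():
            # degenerate blob: fall back to a single-pixel skeleton at the max-distance point
            skel = np.zeros_like(sel)
            skel[np.unravel_index(np.argmax(dist * sel), sel.shape)] = True
        obj.skeleton_length_px = max(_skeleton_path_length(skel), 1.0)
        obj.mean_width_px = max(float(2.0 * dist[skel].mean() - 1.0), 1.0)
        obj.elongation = obj.skeleton_length_px / max(obj.mean_width_px, 1e-9)
    return objs


def classify_objects(
    objs: LabeledObjects,
    min_elongation: float = 5.0,
    min_length_um: float = 50.0,
    width_range_um: tuple[float, float] = (2.0, 12.0),
    um_per_px: float = 0.32,
) -> LabeledObjects:
    """Two-tier classification: filamentous, then of-interest.

    An object is *filamentous* when its elongation (skeleton length / mean
    width) reaches ``min_elongation``; a filamentous object is *of interest*
    when additionally its skeleton length is at least ``min_length_um`` and its
    mean width lies within ``width_range_um``.
    """
    if um_per_px <= 0:
        raise ConfigError("um_per_px must be positive")
    lo_w, hi_w = width_range_um
    for obj in objs.objects:
        obj.is_filamentous = obj.elongation >= min_elongation
        length_um = obj.skeleton_length_px * um_per_px
        width_um = obj.mean_width_px * um_per_px
        obj.is_of_interest = (
            obj.is_filamentous and length_um >= min_length_um and lo_w <= width_um <= hi_w
        )
    return objs


def area_fractions(objs: LabeledObjects) -> dict[str, float]:
    """Area and count fractions of interesting material among all objects.

    Returns ``filament_area_fraction`` (percent of total object area held by
    objects of interest) and ``filamentous_object_fraction`` (percent of
    objects classified filamentous).  NaN (missing), not 0, when there are no
    objects.
    """
    total = sum(o.area_px for o in objs.objects)
    if total == 0:
        return {"filament_area_fraction": float("nan"),
                "filamentous_object_fraction": float("nan")}
    interest = sum(o.area_px for o in objs.objects if o.is_of_interest)
    n_fil = sum(1 for o in objs.objects if o.is_filamentous)
    return {
        "filament_area_fraction": 100.0 * interest / total,
        "filamentous_object_fraction": 100.0 * n_fil / len(objs.objects),
    }
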