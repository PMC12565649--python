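"""Partition the 2-D latent plane into thrombus-state regions.

Two simple polygons designate the *no-thrombus* and *fully thrombosed*
regions; the *partially thrombosed* state is the complement of both, which
makes classification total over the plane.  Membership uses even-odd
(ray-casting) semantics with boundary points counting as inside, and the
precedence no_thrombus > thrombosed > partial breaks any residual ties.

In the published workflow the region boundaries were drawn manually once for
the cohort.  Here they can either be loaded from a JSON region file (exact
reproduction of a chosen partition) or fitted automatically from a small
labeled calibration set as margin-dilated convex hulls of the reference
encodings.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon as ShapelyPolygon

from .data import (
    STATE_NO_THROMBUS,
    STATE_PARTIAL,
    STATE_THROMBOSED,
    LatentPoint,
)

_OVERLAP_TOL = 1e-9
_EDGE_EPS = 1e-12

REGION_FILE_VERSION = 1


def _as_vertices(polygon: Sequence[Sequence[float]]) -> np.ndarray:
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError(
            f"polygon must be an (n>=3, 2) vertex list, got shape {verts.shape}"
        )
    if not np.isfinite(verts).all():
        raise ValueError("polygon vertices must be finite")
    return verts


def _validate_simple(verts: np.ndarray, name: str) -> ShapelyPolygon:
    poly = ShapelyPolygon(verts)
    if poly.area <= _OVERLAP_TOL:
        raise ValueError(f"{name} polygon is degenerate (zero area)")
    if not poly.is_simple or not poly.is_valid:
        raise ValueError(f"{name} polygon is self-intersecting or invalid")
    return poly


def point_in_polygon(p: Sequence[float], polygon: Sequence[Sequence[float]]) -> bool:
    """Even-odd membership test; edge and vertex points count as inside."""
    verts = _as_vertices(polygon)
    _validate_simple(verts, "membership")
    px, py = float(p[0]), float(p[1])
    n = verts.shape[0]
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-segment check (boundary counts as inside)
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        seg2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
        if abs(cross) <= _EDGE_EPS * max(1.0, seg2):
            dot = (px - x1) * (x2 - x1) + (py - y1) * (y2 - y1)
            if -_EDGE_EPS <= dot <= seg2 + _EDGE_EPS:
                return True
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


@dataclass(frozen=True)
class RegionSet:
    """Labeled polygons partitioning the latent plane.

    The partial region is implicit: everything outside both polygons.
    Construction fails if the polygon interiors overlap.
    """

    no_thrombus_polygon: np.ndarray
    thrombosed_polygon: np.ndarray

    def __post_init__(self) -> None:
        nt = _as_vertices(self.no_thrombus_polygon)
        th = _as_vertices(self.thrombosed_polygon)
        p_nt = _validate_simple(nt, "no_thrombus")
        p_th = _validate_simple(th, "thrombosed")
        if p_nt.intersection(p_th).area > _OVERLAP_TOL:
            raise ValueError(
                "no_thrombus and thrombosed polygons overlap "
                f"(area {p_nt.intersection(p_th).area:.3g})"
            )
        object.__setattr__(self, "no_thrombus_polygon", nt)
        object.__setattr__(self, "thrombosed_polygon", th)

    def classify(self, point: LatentPoint | Sequence[float]) -> str:
        return classify(point, self)


def classify(point: LatentPoint | Sequence[float], regions: RegionSet) -> str:
    """Total classification with precedence no_thrombus > thrombosed > partial."""
    p = point.as_array() if isinstance(point, LatentPoint) else np.asarray(point, float)
    if point_in_polygon(p, regions.no_thrombus_polygon):
        return STATE_NO_THROMBUS
    if point_in_polygon(p, regions.thrombosed_polygon):
        return STATE_THROMBOSED
    return STATE_PARTIAL


def _hull_vertices(points: np.ndarray, label: str) -> np.ndarray:
    if points.shape[0] < 3:
        raise ValueError(
            f"need >= 3 reference points for class {label!r}, got {points.shape[0]}"
        )
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError(
            f"reference points for class {label!r} are degenerate "
            "(collinear or coincident); cannot build a region polygon"
        ) from exc
    return points[hull.vertices]


def _dilate(verts: np.ndarray, margin: float) -> np.ndarray:
    if margin == 0:
        return verts
    poly = ShapelyPolygon(verts).buffer(margin, quad_segs=4)
    return np.asarray(poly.exterior.coords[:-1], dtype=float)


def fit_regions(
    labeled_points: Iterable[tuple[LatentPoint | Sequence[float], str]],
    margin: float = 0.0,
) -> RegionSet:
    """Fit regions as margin-dilated convex hulls of labeled encodings.

    ``labeled_points`` pairs latent points with reference state labels; only
    the no_thrombus and thrombosed classes contribute vertices (the partial
    region is the complement by construction).  Raises if either class has
    fewer than three points, is degenerate, or if the dilated hulls overlap.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    groups: dict[str, list[np.ndarray]] = {STATE_NO_THROMBUS: [], STATE_THROMBOSED: []}
    for point, label in labeled_points:
        if label in groups:
            p = point.as_array() if isinstance(point, LatentPoint) else np.asarray(point, float)
            groups[label].append(p)
    nt = _hull_vertices(np.asarray(groups[STATE_NO_THROMBUS], float), STATE_NO_THROMBUS)
    th = _hull_vertices(np.asarray(groups[STATE_THROMBOSED], float), STATE_THROMBOSED)
    return RegionSet(
        no_thrombus_polygon=_dilate(nt, margin),
        thrombosed_polygon=_dilate(th, margin),
    )


def save_regions(regions: RegionSet, path: str) -> None:
    """Write the region polygons as versioned JSON."""
    payload = {
        "version": REGION_FILE_VERSION,
        "no_thrombus_polygon": regions.no_thrombus_polygon.tolist(),
        "thrombosed_polygon": regions.thrombosed_polygon.tolist(),
    }
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_regions(path: str) -> RegionSet:
    """Load and validate a region file (overlap and degeneracy re-checked)."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed region file {path!r}: {exc}") from exc
    try:
        nt = payload["no_thrombus_polygon"]
        th = payload["thrombosed_polygon"]
    except (KeyError, TypeError) as exc:
        raise ValueError(
            f"region file {path!r} is missing required polygon entries"
        ) from exc
    return RegionSet(no_thrombus_polygon=np.asarray(nt, float),
                     thrombosed_polygon=np.asarray(th, float))
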