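"""Cell- and organ-level shape metrics for antheridium burst analysis.

Implements the measurements reported for jacket cells and the whole organ:
polygon areas (shoelace), polyline arc lengths, per-cell width / length /
width-to-length ratio, signed wall curvature from a total-least-squares
circle fit, angles between adjacent outer walls, the apex outer-wall
extension time series, and percent changes between the pre- and post-burst
configurations.

Conventions
-----------
* A jacket cell is a closed simple polygon chained from four wall
  polylines: inner (cavity-facing), outer (surface), and two laterals.
* Cell *width* is the distance between the arc-length centroids of the
  outer and inner walls (the radial chord); cell *length* is the distance
  between the lateral-wall centroids (the axial chord).
* Curvature is signed positive when the wall bulges toward a cavity
  reference point, negative when it bulges away, zero for straight walls.
* All metrics are invariant under rigid transforms of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import least_squares

from .exceptions import GeometryError, InputError
from .geometry import WALL_KINDS, LandmarkGeometry

__all__ = [
    "WallPolyline",
    "JacketCellPolygon",
    "METRIC_COLUMNS",
    "polygon_area",
    "polyline_arclength",
    "polyline_centroid",
    "percent_change",
    "cell_width_length",
    "wall_curvature",
    "wall_angle",
    "apex_extension_series",
    "cell_area_extension",
    "extract_cells",
    "extract_structure",
    "burst_metrics",
]

#: Column schema of the tidy metric table every analysis stage emits.
METRIC_COLUMNS = ["specimen_id", "frame", "cell_id", "metric", "value", "units"]

_CLOSURE_TOL = 1e-6  # µm, wall-chaining tolerance for cell polygons


@dataclass
class WallPolyline:
    """One wall of a jacket cell as an ordered open polyline (µm)."""

    points: np.ndarray
    wall: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise InputError("a wall polyline needs an (m>=2, 2) point array")
        if not np.all(np.isfinite(pts)):
            raise InputError("wall coordinates must be finite")
        seg = np.diff(pts, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise InputError(f"wall {self.wall!r} of cell {self.cell_id!r}: "
                             "consecutive points must be distinct")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def reversed(self) -> "WallPolyline":
        return WallPolyline(self.points[::-1], self.wall, self.cell_id)


@dataclass
class JacketCellPolygon:
    """A jacket cell partitioned into its four walls.

    Wall endpoints must chain into a closed simple polygon:
    inner -> lateral_b -> reversed outer -> reversed lateral_a -> inner.
    (Laterals run from their inner-wall end to their outer-wall end.)
    """

    inner: WallPolyline
    outer: WallPolyline
    lateral_a: WallPolyline
    lateral_b: WallPolyline
    cell_id: str = ""

    def __post_init__(self) -> None:
        ring = self.ring()
        poly = shapely.Polygon(ring)
        if not poly.is_valid or poly.area == 0.0:
            raise GeometryError(
                f"cell {self.cell_id!r}: walls do not form a simple polygon"
            )

    def ring(self) -> np.ndarray:
        """Closed vertex ring chained from the four walls (duplicate
        junction vertices dropped, last vertex != first)."""
        chain = [
            self.inner.points,
            self.lateral_b.points,
            self.outer.points[::-1],
            self.lateral_a.points[::-1],
        ]
        ring = [chain[0]]
        for prev, nxt in zip(chain, chain[1:]):
            if np.linalg.norm(prev[-1] - nxt[0]) > _CLOSURE_TOL:
                raise GeometryError(
                    f"cell {self.cell_id!r}: wall endpoints do not chain "
                    f"(gap {np.linalg.norm(prev[-1] - nxt[0]):.3g} µm)"
                )
            ring.append(nxt[1:])
        ring = np.vstack(ring)
        if np.linalg.norm(ring[-1] - ring[0]) > _CLOSURE_TOL:
            raise GeometryError(f"cell {self.cell_id!r}: polygon not closed")
        if np.linalg.norm(ring[-1] - ring[0]) > 0:
            # tolerate sub-tolerance mismatch by snapping
            ring = ring.copy()
            ring[-1] = ring[0]
        return ring[:-1]

    def walls(self) -> dict:
        return {
            "inner": self.inner,
            "outer": self.outer,
            "lateral_a": self.lateral_a,
            "lateral_b": self.lateral_b,
        }


# ---------------------------------------------------------------------------
# elementary measures


def polygon_area(outline) -> float:
    """Absolute shoelace area (µm²) of a simple polygon.

    ``outline`` is a vertex sequence; a repeated first vertex at the end is
    accepted.  Self-intersecting input raises :class:`GeometryError`.
    """
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("polygon outline must be an (n, 2) array")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise InputError("a polygon needs at least 3 vertices")
    if not shapely.Polygon(pts).is_valid:
        raise GeometryError("polygon is self-intersecting or degenerate")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def polyline_arclength(wall) -> float:
    """Total length (µm) of a polyline (WallPolyline or point array)."""
    pts = wall.points if isinstance(wall, WallPolyline) else np.asarray(wall, float)
    if pts.ndim != 2 or len(pts) < 2:
        raise InputError("a polyline needs at least 2 points")
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def polyline_centroid(wall) -> np.ndarray:
    """Arc-length-weighted centroid of a polyline.

    Weighting by segment length makes the centroid independent of how
    densely the wall was sampled, unlike a plain vertex mean.
    """
    pts = wall.points if isinstance(wall, WallPolyline) else np.asarray(wall, float)
    seg = np.diff(pts, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    total = lens.sum()
    if total == 0.0:
        raise GeometryError("zero-length polyline has no centroid")
    mids = (pts[:-1] + pts[1:]) / 2.0
    return (mids * lens[:, None]).sum(axis=0) / total


def percent_change(before: float, after: float) -> float:
    """Relative change from *before* to *after* in percent."""
    if before == 0.0:
        raise InputError("percent change undefined for a zero baseline")
    return (after - before) / before * 100.0


# ---------------------------------------------------------------------------
# cell metrics


def cell_width_length(cell: JacketCellPolygon) -> tuple[float, float, float]:
    """(width, length, width/length ratio) of one jacket cell.

    Width spans the outer-to-inner wall centroids (radial direction),
    length spans the two lateral-wall centroids (axial direction).
    """
    width = float(np.linalg.norm(
        polyline_centroid(cell.outer) - polyline_centroid(cell.inner)))
    length = float(np.linalg.norm(
        polyline_centroid(cell.lateral_a) - polyline_centroid(cell.lateral_b)))
    if width == 0.0 or length == 0.0:
        raise GeometryError(f"cell {cell.cell_id!r}: degenerate width/length axis")
    return width, length, width / length


def _fit_circle(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares circle fit: Taubin algebraic seed refined by
    geometric (orthogonal-distance) Gauss-Newton.  Returns (center, R)."""
    centroid = pts.mean(axis=0)
    u = pts - centroid
    z = (u ** 2).sum(axis=1)
    # Taubin fit: solve the constrained eigenproblem via Newton on the
    # characteristic polynomial (Chernov's formulation).
    zm = z.mean()
    zu = np.column_stack([z - zm, u])
    m = zu.T @ zu / len(pts)
    mzz, mxz, myz = m[0, 0], m[0, 1], m[0, 2]
    mxx, mxy, myy = m[1, 1], m[1, 2], m[2, 2]
    # characteristic polynomial coefficients for the Taubin eigenvalue
    c0 = mzz * mxy ** 2 + mxz ** 2 * myy + myz ** 2 * mxx \
        - mzz * mxx * myy - 2 * mxz * myz * mxy
    c1 = mxx * myy - mxy ** 2 + mzz * (mxx + myy) - mxz ** 2 - myz ** 2
    c2 = -(mxx + myy)
    eta = 0.0
    for _ in range(50):
        poly = c0 + eta * (c1 + eta * (c2 + eta))
        dpoly = c1 + eta * (2 * c2 + 3 * eta)
        step = poly / dpoly if dpoly != 0 else 0.0
        eta -= step
        if abs(step) < 1e-14 * (1 + abs(eta)):
            break
    det = (mxx - eta) * (myy - eta) - mxy ** 2
    if det == 0.0:
        cx, cy = 0.0, 0.0
    else:
        cx = (mxz * (myy - eta) - myz * mxy) / det / 2.0
        cy = (myz * (mxx - eta) - mxz * mxy) / det / 2.0
    center0 = np.array([cx, cy])

    def residuals(c):
        return np.hypot(*(u - c).T) - np.hypot(*(u - c).T).mean()

    sol = least_squares(residuals, center0, method="lm", xtol=1e-14, ftol=1e-14)
    center = sol.x
    radius = float(np.hypot(*(u - center).T).mean())
    return center + centroid, radius


def wall_curvature(wall: WallPolyline, cavity_ref) -> float:
    """Signed curvature (1/µm) of a wall from a circle fit.

    Magnitude is 1/R of the total-least-squares circle through the wall
    points; the sign is positive when the wall bulges toward
    ``cavity_ref`` and negative when it bulges away.  Collinear walls
    return 0.
    """
    pts = wall.points if isinstance(wall, WallPolyline) else np.asarray(wall, float)
    if len(pts) < 3:
        raise InputError("curvature needs at least 3 wall points")
    ref = np.asarray(cavity_ref, dtype=float)
    chord = pts[-1] - pts[0]
    span = np.linalg.norm(chord)
    if span == 0.0:
        raise InputError("wall endpoints coincide; curvature chord undefined")
    # collinearity: perpendicular offsets of interior points from the chord
    rel = pts - pts[0]
    offsets = (chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / span
    if np.max(np.abs(offsets)) <= 1e-9 * max(span, 1.0):
        return 0.0
    _, radius = _fit_circle(pts)
    # bulge side: net perpendicular offset of the wall's interior
    bulge = float(np.sum(offsets))
    rel_ref = ref - pts[0]
    ref_side = float((chord[0] * rel_ref[1] - chord[1] * rel_ref[0]) / span)
    if bulge == 0.0 or ref_side == 0.0:
        raise GeometryError("cavity reference lies on the wall chord; sign ambiguous")
    sign = 1.0 if np.sign(bulge) == np.sign(ref_side) else -1.0
    return sign / radius


def wall_angle(wall_a: WallPolyline, wall_b: WallPolyline) -> float:
    """Angle (degrees) between two walls at their shared junction.

    Uses the end-to-end chord of each wall, both oriented away from the
    junction endpoint the walls share (within 1e-6 µm).
    """
    pa = wall_a.points if isinstance(wall_a, WallPolyline) else np.asarray(wall_a, float)
    pb = wall_b.points if isinstance(wall_b, WallPolyline) else np.asarray(wall_b, float)
    ends_a = {"first": pa[0], "last": pa[-1]}
    ends_b = {"first": pb[0], "last": pb[-1]}
    junction = None
    for ka, ea in ends_a.items():
        for kb, eb in ends_b.items():
            if np.linalg.norm(ea - eb) <= _CLOSURE_TOL:
                junction = (ka, kb)
                break
        if junction:
            break
    if junction is None:
        raise InputError("walls share no junction endpoint within 1e-6 µm")
    va = (pa[-1] - pa[0]) if junction[0] == "first" else (pa[0] - pa[-1])
    vb = (pb[-1] - pb[0]) if junction[1] == "first" else (pb[0] - pb[-1])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise InputError("zero-length wall chord; angle undefined")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def apex_extension_series(
    walls: Sequence, times: Sequence[float]
) -> tuple[np.ndarray, float, float]:
    """Apex outer-wall arc-length series and its growth to maximum.

    Returns ``(arclengths, percent_change_to_max, seconds_to_max)`` where
    the percent change compares the first frame against the frame of
    maximum length and the elapsed time spans the same interval.
    """
    walls = list(walls)
    times = np.asarray(list(times), dtype=float)
    if len(walls) < 2 or len(walls) != len(times):
        raise InputError("need >= 2 frames with matching times")
    lengths = np.array([polyline_arclength(w) for w in walls])
    imax = int(np.argmax(lengths))
    return lengths, percent_change(lengths[0], lengths[imax]), float(times[imax] - times[0])


def cell_area_extension(before: JacketCellPolygon, after: JacketCellPolygon) -> float:
    """Percent change of a jacket cell's polygon area across burst."""
    if before.cell_id != after.cell_id:
        raise InputError(
            f"cell identity mismatch: {before.cell_id!r} vs {after.cell_id!r}"
        )
    return percent_change(polygon_area(before.ring()), polygon_area(after.ring()))


# ---------------------------------------------------------------------------
# geometry -> metric table plumbing


def extract_structure(geom: LandmarkGeometry, structure: str) -> np.ndarray:
    """Points of one structure tag, in stored order."""
    sel = geom.structure == structure
    if not np.any(sel):
        raise InputError(f"geometry has no {structure!r} landmarks")
    return geom.points[sel]


def extract_cells(geom: LandmarkGeometry) -> list:
    """Assemble every labelled jacket cell into a JacketCellPolygon."""
    cells = []
    cell_sel = geom.structure == "cell"
    for cid in sorted(set(geom.cell_id[cell_sel])):
        walls = {}
        for wk in WALL_KINDS:
            sel = cell_sel & (geom.cell_id == cid) & (geom.wall == wk)
            if not np.any(sel):
                raise InputError(f"cell {cid!r} is missing its {wk} wall")
            walls[wk] = WallPolyline(geom.points[sel], wall=wk, cell_id=cid)
        cells.append(JacketCellPolygon(cell_id=cid, **walls))
    return cells


def _organ_width(outline: np.ndarray) -> float:
    """Extent of the (normalized) organ outline along the x-axis."""
    return float(outline[:, 0].max() - outline[:, 0].min())


def burst_metrics(
    before: LandmarkGeometry, after: LandmarkGeometry
) -> pd.DataFrame:
    """Tidy per-cell and organ-level percent changes across burst.

    Expects a *normalized* before/after pair with identical layout.
    Emits one row per (cell, metric) plus organ rows, in the schema
    :data:`METRIC_COLUMNS`.
    """
    if not before.same_layout(after):
        raise InputError("before/after geometries differ in landmark layout")
    rows = []

    def add(cell_id, metric, value, units):
        rows.append(
            {
                "specimen_id": before.specimen_id,
                "frame": after.frame,
                "cell_id": cell_id,
                "metric": metric,
                "value": float(value),
                "units": units,
            }
        )

    cells_before = {c.cell_id: c for c in extract_cells(before)}
    cells_after = {c.cell_id: c for c in extract_cells(after)}
    cavity_b = extract_structure(before, "cavity")
    cavity_ref = cavity_b.mean(axis=0)
    for cid in sorted(cells_before):
        cb, ca = cells_before[cid], cells_after[cid]
        wb, lb, rb = cell_width_length(cb)
        wa, la, ra = cell_width_length(ca)
        add(cid, "cell_width_change", percent_change(wb, wa), "%")
        add(cid, "cell_length_change", percent_change(lb, la), "%")
        add(cid, "cell_ratio_change", percent_change(rb, ra), "%")
        add(cid, "cell_area_extension", cell_area_extension(cb, ca), "%")
        add(cid, "inner_curvature_before", wall_curvature(cb.inner, cavity_ref), "1/µm")
        add(cid, "inner_curvature_after", wall_curvature(ca.inner, cavity_ref), "1/µm")

    outline_b = extract_structure(before, "organ_outline")
    outline_a = extract_structure(after, "organ_outline")
    add("", "organ_area_change",
        percent_change(polygon_area(outline_b), polygon_area(outline_a)), "%")
    add("", "organ_width_change",
        percent_change(_organ_width(outline_b), _organ_width(outline_a)), "%")
    cavity_a = extract_structure(after, "cavity")
    add("", "cavity_area_change",
        percent_change(polygon_area(cavity_b), polygon_area(cavity_a)), "%")
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
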