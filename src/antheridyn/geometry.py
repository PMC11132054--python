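"""Landmark geometries and rigid normalization of antheridium outlines.

An antheridium traced from a time-lapse micrograph is an ordered set of 2-D
landmarks (µm): the organ outline, the cavity outline, per-jacket-cell wall
polylines and the apex outer wall.  Because specimens are imaged at arbitrary
orientations, geometries are registered into a canonical pose before any
averaging: the two bottom anchor landmarks define a tilt angle

    theta = arctan((y_r - y_l) / (x_r - x_l))      in (-pi/2, pi/2)

and a center c (their midpoint); every landmark p is replaced by the
clockwise rotation R(theta) @ (p - c), which puts the anchors symmetrically
on the x-axis with the apex on top.  Mean shapes are per-index landmark
averages over specimens, and the burst deformation field is the per-index
difference of the mean shapes immediately before and after burst.

All coordinates are micrometres, times are seconds, angles radians unless a
function says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CorrespondenceError, InputError, OrientationError

__all__ = [
    "STRUCTURES",
    "WALL_KINDS",
    "LandmarkGeometry",
    "GeometrySeries",
    "NormalizationResult",
    "MeanShapeModel",
    "DeformationField",
    "orientation_angle",
    "anchor_center",
    "normalize_geometry",
    "normalize_series",
    "mean_shape",
    "burst_dynamics",
    "displacement_stats",
]

#: Structure tags a landmark may carry, in canonical ordering.
STRUCTURES = ("organ_outline", "cavity", "apex_outer_wall", "cell")

#: Wall tags for landmarks belonging to a jacket cell, in canonical ordering.
WALL_KINDS = ("inner", "outer", "lateral_a", "lateral_b")


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError(f"points must be an (n, 2) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InputError("landmark coordinates must be finite")
    return pts


def _as_str_array(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=object)
    if arr.shape != (n,):
        raise InputError(f"{name} must have one entry per landmark ({n}), got {arr.shape}")
    return np.asarray([str(v) if v is not None else "" for v in arr], dtype=object)


@dataclass
class LandmarkGeometry:
    """Ordered landmarks of one specimen at one frame.

    Parameters
    ----------
    specimen_id:
        Identifier of the antheridium (the index *k*).
    frame:
        1-based frame number within the series.
    time_s:
        Acquisition time in seconds.
    points:
        ``(n, 2)`` float array of landmark coordinates in µm; landmark
        correspondence across frames and specimens is by row index.
    structure:
        Per-landmark structure tag, one of :data:`STRUCTURES`.
    cell_id:
        Per-landmark cell identifier; empty string outside cells.
    wall:
        Per-landmark wall tag (:data:`WALL_KINDS`); empty string outside
        cells.
    anchor_left, anchor_right:
        0-based indices of the bottom-left and bottom-right anchor
        landmarks used for normalization.
    """

    specimen_id: str
    frame: int
    time_s: float
    points: np.ndarray
    structure: np.ndarray
    cell_id: np.ndarray = None  # type: ignore[assignment]
    wall: np.ndarray = None  # type: ignore[assignment]
    anchor_left: int = 0
    anchor_right: int = 1

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        n = self.n
        if n < 3:
            raise InputError(f"geometry needs at least 3 landmarks, got {n}")
        self.structure = _as_str_array(self.structure, n, "structure")
        unknown = set(self.structure) - set(STRUCTURES)
        if unknown:
            raise InputError(f"unknown structure tags {sorted(unknown)}")
        self.cell_id = (
            np.asarray([""] * n, dtype=object)
            if self.cell_id is None
            else _as_str_array(self.cell_id, n, "cell_id")
        )
        self.wall = (
            np.asarray([""] * n, dtype=object)
            if self.wall is None
            else _as_str_array(self.wall, n, "wall")
        )
        bad_wall = set(self.wall) - set(WALL_KINDS) - {""}
        if bad_wall:
            raise InputError(f"unknown wall tags {sorted(bad_wall)}")
        l, r = int(self.anchor_left), int(self.anchor_right)
        if l == r:
            raise InputError("anchor_left and anchor_right must differ")
        for name, idx in (("anchor_left", l), ("anchor_right", r)):
            if not 0 <= idx < n:
                raise InputError(f"{name}={idx} outside 0..{n - 1}")
        if np.allclose(self.points[l], self.points[r]):
            raise InputError(
                f"anchor points coincide for specimen {self.specimen_id!r} frame {self.frame}"
            )
        self.anchor_left, self.anchor_right = l, r
        self.frame = int(self.frame)
        self.time_s = float(self.time_s)
        self.specimen_id = str(self.specimen_id)

    @property
    def n(self) -> int:
        return len(self.points)

    def same_layout(self, other: "LandmarkGeometry") -> bool:
        """True when landmark correspondence by index is meaningful."""
        return (
            self.n == other.n
            and np.array_equal(self.structure, other.structure)
            and np.array_equal(self.cell_id, other.cell_id)
            and np.array_equal(self.wall, other.wall)
            and self.anchor_left == other.anchor_left
            and self.anchor_right == other.anchor_right
        )

    def with_points(self, points: np.ndarray, **overrides) -> "LandmarkGeometry":
        """Copy of this geometry with new coordinates (labels shared)."""
        kw = dict(
            specimen_id=self.specimen_id,
            frame=self.frame,
            time_s=self.time_s,
            points=points,
            structure=self.structure,
            cell_id=self.cell_id,
            wall=self.wall,
            anchor_left=self.anchor_left,
            anchor_right=self.anchor_right,
        )
        kw.update(overrides)
        return LandmarkGeometry(**kw)


@dataclass
class GeometrySeries:
    """Time-ordered frames of one specimen with index correspondence."""

    specimen_id: str
    frames: list

    def __post_init__(self) -> None:
        if not self.frames:
            raise InputError("a GeometrySeries needs at least one frame")
        first = self.frames[0]
        times = [g.time_s for g in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise InputError(
                f"specimen {self.specimen_id!r}: time_s must be strictly increasing"
            )
        for g in self.frames[1:]:
            if not first.same_layout(g):
                raise CorrespondenceError(
                    f"specimen {self.specimen_id!r}: frame {g.frame} layout differs "
                    f"from frame {first.frame}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class NormalizationResult:
    """Rigid transform that maps a geometry into the canonical pose.

    ``theta`` is the Eq.-style tilt in (-pi/2, pi/2); ``flipped`` records
    whether an extra rotation by pi was applied to put the apex on top.
    """

    theta: float
    center: np.ndarray
    flipped: bool
    normalized: LandmarkGeometry

    def to_sidecar(self) -> dict:
        """JSON-serialisable per-specimen transform record."""
        return {
            "specimen_id": self.normalized.specimen_id,
            "theta_rad": float(self.theta),
            "center_x_um": float(self.center[0]),
            "center_y_um": float(self.center[1]),
            "flipped": bool(self.flipped),
        }


@dataclass
class MeanShapeModel:
    """Per-index average of normalized geometries (the geometry model)."""

    points: np.ndarray
    n_specimens: int
    structure: np.ndarray
    cell_id: np.ndarray
    wall: np.ndarray

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class DeformationField:
    """Per-landmark displacement vectors between two mean shapes (µm)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = _as_points(self.vectors)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.hypot(self.vectors[:, 0], self.vectors[:, 1])

    def __len__(self) -> int:
        return len(self.vectors)


# ---------------------------------------------------------------------------
# operations


def orientation_angle(anchor_left, anchor_right, *, context: str = "") -> float:
    """Tilt angle of the anchor line against the x-axis, in (-pi/2, pi/2).

    ``arctan`` of the slope between the bottom-left and bottom-right anchor
    points.  Raises :class:`OrientationError` when the anchors share an
    x-coordinate (vertical line, undefined slope).
    """
    al = np.asarray(anchor_left, dtype=float)
    ar = np.asarray(anchor_right, dtype=float)
    dx = ar[0] - al[0]
    if dx == 0.0:
        where = f" ({context})" if context else ""
        raise OrientationError(f"anchor x-coordinates coincide{where}: tilt undefined")
    return float(np.arctan((ar[1] - al[1]) / dx))


def anchor_center(anchor_left, anchor_right) -> np.ndarray:
    """Midpoint of the two bottom anchor points."""
    al = np.asarray(anchor_left, dtype=float)
    ar = np.asarray(anchor_right, dtype=float)
    return (al + ar) / 2.0


def _clockwise_rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


def _pose_from_anchors(geom: LandmarkGeometry) -> tuple[float, np.ndarray]:
    """(theta, center) from a geometry's anchors, left/right by x order."""
    pl = geom.points[geom.anchor_left]
    pr = geom.points[geom.anchor_right]
    # keep Eq.-style arctan well defined: the anchor with smaller x is "left"
    if pr[0] < pl[0]:
        pl, pr = pr, pl
    ctx = f"specimen {geom.specimen_id!r} frame {geom.frame}"
    theta = orientation_angle(pl, pr, context=ctx)
    center = anchor_center(pl, pr)
    return theta, center


def _apply_pose(
    geom: LandmarkGeometry, theta: float, center: np.ndarray, flipped: bool
) -> LandmarkGeometry:
    rot = _clockwise_rotation(theta)
    pts = (geom.points - center) @ rot.T
    if flipped:
        pts = -pts
    return geom.with_points(pts)


def _needs_flip(geom: LandmarkGeometry, theta: float, center: np.ndarray) -> bool:
    """Apex-up rule: flip by pi when apex landmarks end below the x-axis.

    Geometries without apex-tagged landmarks are never flipped.
    """
    apex = geom.structure == "apex_outer_wall"
    if not np.any(apex):
        return False
    rot = _clockwise_rotation(theta)
    y_mean = float(np.mean(((geom.points[apex] - center) @ rot.T)[:, 1]))
    if y_mean == 0.0:
        raise OrientationError(
            f"specimen {geom.specimen_id!r} frame {geom.frame}: apex landmarks "
            "lie on the anchor axis; orientation ambiguous"
        )
    return y_mean < 0.0


def normalize_geometry(geom: LandmarkGeometry) -> NormalizationResult:
    """Register one geometry into the canonical (apex-up, symmetric) pose.

    Every landmark p becomes ``R(theta) @ (p - c)`` with the clockwise
    rotation R; afterwards the anchors sit at (-d/2, 0) and (+d/2, 0) and
    apex landmarks, when present, have positive mean y (an extra rotation
    by pi is applied otherwise and reported as ``flipped``).
    """
    theta, center = _pose_from_anchors(geom)
    flipped = _needs_flip(geom, theta, center)
    return NormalizationResult(
        theta=theta,
        center=center,
        flipped=flipped,
        normalized=_apply_pose(geom, theta, center, flipped),
    )


def normalize_series(series: GeometrySeries) -> tuple[GeometrySeries, NormalizationResult]:
    """Rigidly register a whole series using the first frame's anchors.

    The tilt and center are estimated from frame 1 only and the same rigid
    transform is applied to every frame, so inter-frame deformation is
    preserved exactly.  Returns the registered series and the transform
    (whose ``normalized`` field holds frame 1).
    """
    first = series.frames[0]
    theta, center = _pose_from_anchors(first)
    flipped = _needs_flip(first, theta, center)
    frames = [_apply_pose(g, theta, center, flipped) for g in series.frames]
    result = NormalizationResult(theta, center, flipped, frames[0])
    return GeometrySeries(series.specimen_id, frames), result


def mean_shape(geoms: Sequence[LandmarkGeometry]) -> MeanShapeModel:
    """Per-index arithmetic mean of corresponding landmarks.

    All geometries must share landmark count and label layout; violations
    raise :class:`CorrespondenceError` naming the offending specimens.
    """
    geoms = list(geoms)
    if not geoms:
        raise InputError("mean_shape needs at least one geometry")
    first = geoms[0]
    bad = [g.specimen_id for g in geoms[1:] if not first.same_layout(g)]
    if bad:
        raise CorrespondenceError(
            f"landmark layout differs from {first.specimen_id!r} for specimens: {bad}"
        )
    if all(np.array_equal(g.points, first.points) for g in geoms[1:]):
        pts = first.points.copy()  # mean of identical inputs is exact
    else:
        pts = np.mean([g.points for g in geoms], axis=0)
    return MeanShapeModel(
        points=pts,
        n_specimens=len(geoms),
        structure=first.structure.copy(),
        cell_id=first.cell_id.copy(),
        wall=first.wall.copy(),
    )


def burst_dynamics(before: MeanShapeModel, after: MeanShapeModel) -> DeformationField:
    """Displacement field between the mean shapes before and after burst."""
    if before.n != after.n:
        raise CorrespondenceError(
            f"mean shapes differ in landmark count: {before.n} vs {after.n}"
        )
    return DeformationField(after.points - before.points)


def displacement_stats(field: DeformationField, labels) -> pd.DataFrame:
    """Mean and s.d. of displacement magnitudes grouped by wall class.

    ``labels`` is a per-landmark class array (e.g. the wall tags of the
    cell landmarks); an empty label anywhere is an error.  Group order is
    deterministic: canonical wall order first, then alphabetical.
    """
    labels = _as_str_array(labels, len(field), "labels")
    if np.any(labels == ""):
        missing = np.flatnonzero(labels == "")[:5].tolist()
        raise InputError(f"unlabeled landmark indices: {missing}")
    mags = field.magnitudes
    order = {w: i for i, w in enumerate(WALL_KINDS)}
    groups = sorted(set(labels), key=lambda g: (order.get(g, len(order)), g))
    rows = []
    for g in groups:
        sel = mags[labels == g]
        rows.append(
            {
                "wall": g,
                "n": int(sel.size),
                "mean_um": float(np.mean(sel)),
                "sd_um": float(np.std(sel, ddof=1)) if sel.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["wall", "n", "mean_um", "sd_um"])
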