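"""Synthetic antheridium geometries and sperm tracks with recorded truth.

Every generator here is a pure function of (scenario, seed) and records the
ground truth it embedded, so each pipeline stage has a recovery test that
needs no microscopy data.  The default :class:`BurstScenario` encodes the
measured population effect sizes of antheridium burst in *P. patens*:

====================  =======  =========================================
parameter             default  meaning
====================  =======  =========================================
width_factor_mean     1.169    mean per-cell jacket-cell width factor
length_factor_mean    0.951    mean per-cell length factor
ratio_factor_mean     1.211    mean per-cell width/length-ratio factor
organ_area_factor     0.906    whole-organ outline area factor
organ_width_factor    0.950    organ width (longitudinal x-extent) factor
cavity_area_factor    0.781    cavity outline area factor
apex_growth           0.073    apex outer-wall relative length increase
apex_duration_s       2.6      seconds from burst onset to apex maximum
frame_rate            15.0     frames per second of the time-lapse
====================  =======  =========================================

Per-cell (width, length) factors are drawn from an equal-weight two-point
mixture calibrated in closed form so that the population means of width,
length AND width/length ratio hit the three targets simultaneously; this
requires positively co-varying components whenever the ratio-of-means
exceeds the mean-of-ratios (see :func:`calibrate_cell_factors`).

The template antheridium is an upright egg-shaped organ outline with a
single ring of quadrilateral jacket cells whose inner walls bow toward the
internal cavity, two apical cells on top, an apex outer-wall polyline and
two bottom anchor landmarks.  The burst deformation rebuilds each cell in
its own local frame with prescribed centroid distances, so the measured
width/length changes equal the drawn factors exactly in noise-free mode
while inner-wall curvature strictly increases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, GenerationError, InputError
from .geometry import GeometrySeries, LandmarkGeometry
from .kinematics import SpermMassTrack, SpermTrack
from .morphometrics import (
    WallPolyline,
    polygon_area,
    polyline_arclength,
    polyline_centroid,
)

__all__ = [
    "BurstScenario",
    "SyntheticTruth",
    "AntheridiumTemplate",
    "calibrate_cell_factors",
    "sample_cell_factors",
    "make_antheridium_template",
    "apply_burst_deformation",
    "rigid_jitter",
    "add_landmark_noise",
    "make_apex_series",
    "make_sperm_mass_track",
    "make_sperm_track",
    "simulate_burst_dataset",
]

_MAX_TILT_DEG = 60.0  # arctan normalization is only exercised well inside ±90°


@dataclass(frozen=True)
class BurstScenario:
    """Generator settings; defaults are the measured burst effect sizes."""

    # template geometry
    n_cells_side: int = 10
    landmarks_per_wall: int = 7
    organ_height_um: float = 45.0
    organ_basal_width_um: float = 30.0
    apex_arc_deg: float = 70.0
    basal_gap_deg: float = 40.0
    cell_depth_um: float = 5.0
    cell_bow: float = 0.25
    cell_fill: float = 0.88
    ring_radius_frac: float = 0.80
    cavity_width_frac: float = 0.55
    cavity_height_frac: float = 0.62
    cavity_center_frac: float = 0.46
    # burst deformation
    width_factor_mean: float = 1.169
    length_factor_mean: float = 0.951
    ratio_factor_mean: float = 1.211
    organ_area_factor: float = 0.906
    organ_width_factor: float = 0.950
    cavity_area_factor: float = 0.781
    curvature_gain: float = 1.3
    # apex swelling
    apex_growth: float = 0.073
    apex_duration_s: float = 2.6
    frame_rate: float = 15.0
    # imaging imperfections
    noise_sigma_um: float = 0.05
    max_tilt_deg: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "width_factor_mean", "length_factor_mean", "ratio_factor_mean",
            "organ_area_factor", "organ_width_factor", "cavity_area_factor",
            "curvature_gain", "frame_rate",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"scenario {name} must be positive")
        if self.noise_sigma_um < 0:
            raise InputError("noise_sigma_um must be >= 0")
        if not 0 <= self.max_tilt_deg <= _MAX_TILT_DEG:
            raise InputError(f"max_tilt_deg must lie in [0, {_MAX_TILT_DEG}]")
        if self.n_cells_side < 1:
            raise InputError("need at least one jacket cell per side")
        if self.landmarks_per_wall < 3:
            raise InputError("need >= 3 landmarks per wall")
        if self.apex_growth < 0:
            raise InputError("apex_growth must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by a generator call."""

    seed: Optional[int] = None
    cell_factors: Optional[pd.DataFrame] = None
    mixture: Optional[dict] = None
    organ_factors: Optional[dict] = None
    displacement: Optional[np.ndarray] = None
    transform: Optional[dict] = None
    apex_growth_percent: Optional[float] = None
    apex_duration_s: Optional[float] = None
    apex_lengths: Optional[np.ndarray] = None
    center_speeds: Optional[np.ndarray] = None
    radius_speeds: Optional[np.ndarray] = None
    end_speeds: Optional[np.ndarray] = None
    sperm_speed: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serialisable dump (arrays to lists, tables to records)."""
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, pd.DataFrame):
                v = v.to_dict(orient="records")
            out[f.name] = v
        return out


@dataclass
class _CellFrame:
    """Local construction frame of one jacket cell in the template ring."""

    cell_id: str
    base: np.ndarray      # world position of the inner-wall chord midpoint
    u: np.ndarray         # tangential unit vector (length axis)
    v: np.ndarray         # outward radial unit vector (width axis)
    half_chord: float     # a: half the inner-wall chord (µm)
    depth: float          # h: outer-wall offset along +v (µm)
    sagitta: float        # s: inner-wall bulge toward the cavity (µm)


@dataclass
class AntheridiumTemplate:
    """Pre-burst geometry plus the construction frames needed to deform it."""

    geometry: LandmarkGeometry
    cells: list
    truth: SyntheticTruth

    @property
    def cell_ids(self) -> list:
        return [c.cell_id for c in self.cells]


# ---------------------------------------------------------------------------
# factor-mixture calibration


def calibrate_cell_factors(scenario: BurstScenario) -> dict:
    """Equal-weight two-point mixture hitting all three factor means.

    With targets W = E[w], L = E[l], R = E[w/l] and symmetric components
    (W ± dw, L ± dl), the ratio constraint is linear in dw at fixed dl:

        dw(dl) = (W*L - R*(L**2 - dl**2)) / dl

    The spread is minimal at dl* = sqrt(L*(W - R*L)/R) when the
    ratio-of-means W/L exceeds R (positive w-l covariance required); when
    R exceeds W/L a constant width with dl* = sqrt(L*(R*L - W)/R) solves
    the system; when R == W/L the mixture degenerates to constant pairs.
    """
    W = scenario.width_factor_mean
    L = scenario.length_factor_mean
    R = scenario.ratio_factor_mean
    A = L * (W - R * L)
    if abs(R - W / L) < 1e-12:
        dw = dl = 0.0
    elif A > 0:
        dl = float(np.sqrt(A / R))
        dw = float(2.0 * np.sqrt(A * R))
    else:
        dl = float(np.sqrt(-A / R))
        dw = 0.0
    pairs = np.array([[W + dw, L + dl], [W - dw, L - dl]])
    if np.any(pairs <= 0):
        raise CalibrationError(
            f"no positive two-point mixture for means (W={W}, L={L}, R={R}); "
            f"components would be {pairs.tolist()}"
        )
    return {
        "weights": [0.5, 0.5],
        "components": pairs.tolist(),
        "delta_w": dw,
        "delta_l": dl,
    }


def sample_cell_factors(
    scenario: BurstScenario, n_cells: int, seed: int
) -> tuple[np.ndarray, dict]:
    """Draw per-cell (width_factor, length_factor) pairs from the mixture."""
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    mixture = calibrate_cell_factors(scenario)
    comps = np.asarray(mixture["components"])
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, 2, size=n_cells)
    return comps[pick], mixture


# ---------------------------------------------------------------------------
# template construction


def _ellipse_point(phi_deg, ax, ay, center, rho=1.0):
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    return np.stack(
        [center[0] + rho * ax * np.cos(phi), center[1] + rho * ay * np.sin(phi)],
        axis=-1,
    )


def _inner_arc(half_chord: float, sagitta: float, m: int) -> np.ndarray:
    """Symmetric arc from (-a, 0) to (a, 0) dipping to (0, -s)."""
    if sagitta <= 0:
        x = np.linspace(-half_chord, half_chord, m)
        return np.column_stack([x, np.zeros(m)])
    radius = (half_chord ** 2 + sagitta ** 2) / (2.0 * sagitta)
    alpha = np.arctan2(half_chord, radius - sagitta)
    t = np.linspace(-alpha, alpha, m)
    arc = np.column_stack(
        [radius * np.sin(t), (radius - sagitta) - radius * np.cos(t)]
    )
    # junction landmarks are shared with the laterals bit-for-bit
    arc[0] = (-half_chord, 0.0)
    arc[-1] = (half_chord, 0.0)
    return arc


def _cell_local_walls(
    half_chord: float, depth: float, sagitta: float, m: int
) -> dict:
    """The four sampled walls of one cell in its local (u, v) frame."""
    inner = _inner_arc(half_chord, sagitta, m)
    x = np.linspace(-half_chord, half_chord, m)
    outer = np.column_stack([x, np.full(m, depth)])
    ys = np.linspace(0.0, depth, m)
    lat_a = np.column_stack([np.full(m, -half_chord), ys])
    lat_b = np.column_stack([np.full(m, half_chord), ys])
    return {"inner": inner, "outer": outer, "lateral_a": lat_a, "lateral_b": lat_b}


def _to_world(local: np.ndarray, frame: _CellFrame) -> np.ndarray:
    return frame.base + np.outer(local[:, 0], frame.u) + np.outer(local[:, 1], frame.v)


def _apex_wall_phi(scenario: BurstScenario, m: int = 15) -> np.ndarray:
    half = scenario.apex_arc_deg / 2.0 + 3.0
    return np.linspace(90.0 - half, 90.0 + half, m)


def make_antheridium_template(scenario: BurstScenario) -> AntheridiumTemplate:
    """Build the upright pre-burst antheridium geometry.

    Deterministic in the scenario (no randomness): an egg-shaped organ
    outline with bottom anchors, an internal cavity outline, the apex
    outer-wall polyline and a ring of 2*n_cells_side jacket cells plus two
    apical cells, each with an inner wall bowed toward the cavity.
    """
    ax_o = scenario.organ_basal_width_um / 2.0
    ay_o = scenario.organ_height_um / 2.0
    c0 = np.array([0.0, ay_o])

    # organ outline: 5-degree sampling starting at the apex, counter-clockwise
    phis = (90.0 + 5.0 * np.arange(72)) % 360.0
    outline = _ellipse_point(phis, ax_o, ay_o, c0)
    anchor_left = int(np.where(np.isclose(phis, 230.0))[0][0])
    anchor_right = int(np.where(np.isclose(phis, 310.0))[0][0])

    cav_ax = scenario.cavity_width_frac * ax_o
    cav_ay = scenario.cavity_height_frac * ay_o
    cav_c = np.array([0.0, scenario.cavity_center_frac * scenario.organ_height_um])
    cavity = _ellipse_point(90.0 + 7.5 * np.arange(48), cav_ax, cav_ay, cav_c)

    apex_wall = _ellipse_point(_apex_wall_phi(scenario), ax_o, ay_o, c0)

    # cell sectors: left side 125..250 deg, right side -70..55 deg,
    # apical pair 55..125 deg; bottom 250..290 deg stays cell-free
    half_apex = scenario.apex_arc_deg / 2.0
    half_gap = scenario.basal_gap_deg / 2.0
    n = scenario.n_cells_side
    left_edges = np.linspace(90.0 + half_apex, 270.0 - half_gap, n + 1)
    right_edges = np.linspace(270.0 + half_gap - 360.0, 90.0 - half_apex, n + 1)
    sectors = (
        [(f"L{i + 1:02d}", left_edges[i], left_edges[i + 1]) for i in range(n)]
        + [(f"R{i + 1:02d}", right_edges[i], right_edges[i + 1]) for i in range(n)]
        + [("AP1", 90.0 - half_apex, 90.0), ("AP2", 90.0, 90.0 + half_apex)]
    )

    m = scenario.landmarks_per_wall
    rho = scenario.ring_radius_frac
    frames, points, structure, cell_id, wall = [], [], [], [], []

    def push(pts, struct, cid="", wl=""):
        points.append(pts)
        structure.extend([struct] * len(pts))
        cell_id.extend([cid] * len(pts))
        wall.extend([wl] * len(pts))

    push(outline, "organ_outline")
    push(cavity, "cavity")
    push(apex_wall, "apex_outer_wall")

    for cid, phi0, phi1 in sectors:
        phi_m = (phi0 + phi1) / 2.0
        base = _ellipse_point(phi_m, ax_o, ay_o, c0, rho=rho)
        pr = np.deg2rad(phi_m)
        tangent = np.array([-ax_o * np.sin(pr), ay_o * np.cos(pr)])
        tangent /= np.linalg.norm(tangent)
        normal = np.array([ay_o * np.cos(pr), ax_o * np.sin(pr)])
        normal /= np.linalg.norm(normal)
        edge0 = _ellipse_point(phi0, ax_o, ay_o, c0, rho=rho)
        edge1 = _ellipse_point(phi1, ax_o, ay_o, c0, rho=rho)
        half_chord = scenario.cell_fill * np.linalg.norm(edge1 - edge0) / 2.0
        if half_chord <= 0:
            raise GenerationError(f"cell {cid}: empty sector")
        sagitta = scenario.cell_bow * half_chord
        depth = scenario.cell_depth_um
        frame = _CellFrame(cid, base, tangent, normal, half_chord, depth, sagitta)
        local = _cell_local_walls(half_chord, depth, sagitta, m)
        for wk in ("inner", "outer", "lateral_a", "lateral_b"):
            push(_to_world(local[wk], frame), "cell", cid, wk)
        frames.append(frame)

    geometry = LandmarkGeometry(
        specimen_id="template",
        frame=1,
        time_s=0.0,
        points=np.vstack(points),
        structure=np.asarray(structure, dtype=object),
        cell_id=np.asarray(cell_id, dtype=object),
        wall=np.asarray(wall, dtype=object),
        anchor_left=anchor_left,
        anchor_right=anchor_right,
    )
    truth = SyntheticTruth(
        seed=None,
        extra={
            "scenario": dataclasses.asdict(scenario),
            "n_cells": len(frames),
        },
    )
    return AntheridiumTemplate(geometry=geometry, cells=frames, truth=truth)


# ---------------------------------------------------------------------------
# burst deformation


def _measured_width(frame: _CellFrame, m: int) -> float:
    """Centroid-to-centroid width of the before cell, in its local frame."""
    local = _cell_local_walls(frame.half_chord, frame.depth, frame.sagitta, m)
    return float(
        polyline_centroid(local["outer"])[1] - polyline_centroid(local["inner"])[1]
    )


def _deformed_cell_walls(
    frame: _CellFrame, w: float, l: float, gain: float, m: int
) -> tuple[dict, dict]:
    """Rebuild one cell after burst; returns (local walls, per-cell truth).

    The inner-wall circle radius shrinks by the curvature gain and the
    outer wall is placed so the centroid-to-centroid width equals exactly
    w times the pre-burst width; the chord shrinks exactly by l.
    """
    a2 = l * frame.half_chord
    r1 = (frame.half_chord ** 2 + frame.sagitta ** 2) / (2.0 * frame.sagitta)
    r2 = r1 / gain
    if r2 <= a2:
        raise GenerationError(
            f"cell {frame.cell_id}: curvature gain {gain} incompatible with "
            f"length factor {l} (fitted radius below half-chord)"
        )
    s2 = r2 - np.sqrt(r2 ** 2 - a2 ** 2)
    inner = _inner_arc(a2, s2, m)
    v_inner = polyline_centroid(inner)[1]
    width0 = _measured_width(frame, m)
    h2 = w * width0 + v_inner
    if h2 <= 0:
        raise GenerationError(
            f"cell {frame.cell_id}: width factor {w} collapses the cell"
        )
    # anchor the cell at its (stiff) outer wall: the outer plane stays at
    # the pre-burst depth and the inner wall extends toward the cavity
    dv = frame.depth - h2
    inner = inner + np.array([0.0, dv])
    x = np.linspace(-a2, a2, m)
    outer = np.column_stack([x, np.full(m, frame.depth)])
    ys = np.linspace(dv, frame.depth, m)
    walls = {
        "inner": inner,
        "outer": outer,
        "lateral_a": np.column_stack([np.full(m, -a2), ys]),
        "lateral_b": np.column_stack([np.full(m, a2), ys]),
    }
    cell_truth = {
        "curvature_before": 1.0 / r1,
        "curvature_after": 1.0 / r2,
        "width_before": width0,
        "width_after": w * width0,
        "length_before": 2.0 * frame.half_chord,
        "length_after": 2.0 * a2,
    }
    return walls, cell_truth


def _scale_about(pts: np.ndarray, center: np.ndarray, fx: float, fy: float) -> np.ndarray:
    out = pts.copy()
    out[:, 0] = center[0] + fx * (pts[:, 0] - center[0])
    out[:, 1] = center[1] + fy * (pts[:, 1] - center[1])
    return out


def apply_burst_deformation(
    template: AntheridiumTemplate, scenario: BurstScenario, seed: int
) -> tuple[LandmarkGeometry, SyntheticTruth]:
    """Deform the template into its post-burst configuration.

    Each jacket cell is rebuilt with its drawn (width, length) factors and
    a strictly increased inner-wall curvature; the organ outline is scaled
    anisotropically to hit the organ area and width factors exactly, the
    cavity isotropically to hit its area factor exactly, and the apex wall
    follows the organ channel.  Landmark noise of ``noise_sigma_um`` is
    then added (seeded); the recorded truth is noise-free.
    """
    geom = template.geometry
    factors, mixture = sample_cell_factors(scenario, len(template.cells), seed)
    m = scenario.landmarks_per_wall
    pts = geom.points.copy()

    outline_sel = geom.structure == "organ_outline"
    apex_sel = geom.structure == "apex_outer_wall"
    cavity_sel = geom.structure == "cavity"
    fx = scenario.organ_width_factor
    fy = scenario.organ_area_factor / scenario.organ_width_factor
    organ_center = geom.points[outline_sel].mean(axis=0)
    pts[outline_sel] = _scale_about(geom.points[outline_sel], organ_center, fx, fy)
    pts[apex_sel] = _scale_about(geom.points[apex_sel], organ_center, fx, fy)
    cav_scale = float(np.sqrt(scenario.cavity_area_factor))
    cav_center = geom.points[cavity_sel].mean(axis=0)
    pts[cavity_sel] = _scale_about(
        geom.points[cavity_sel], cav_center, cav_scale, cav_scale
    )

    rows = []
    for frame, (w, l) in zip(template.cells, factors):
        walls, cell_truth = _deformed_cell_walls(
            frame, float(w), float(l), scenario.curvature_gain, m
        )
        for wk in ("inner", "outer", "lateral_a", "lateral_b"):
            sel = (geom.cell_id == frame.cell_id) & (geom.wall == wk)
            pts[sel] = _to_world(walls[wk], frame)
        before_local = _cell_local_walls(
            frame.half_chord, frame.depth, frame.sagitta, m
        )
        ring_b = _ring_from_walls(before_local)
        ring_a = _ring_from_walls(walls)
        rows.append(
            {
                "cell_id": frame.cell_id,
                "width_factor": float(w),
                "length_factor": float(l),
                "ratio_factor": float(w / l),
                "area_factor": polygon_area(ring_a) / polygon_area(ring_b),
                **cell_truth,
            }
        )

    displacement = pts - geom.points
    if scenario.noise_sigma_um > 0:
        rng = np.random.default_rng(seed)
        pts = _shared_noise(pts, scenario.noise_sigma_um, rng)

    after = geom.with_points(pts, frame=geom.frame + 1, time_s=geom.time_s + 8.0)
    truth = SyntheticTruth(
        seed=seed,
        cell_factors=pd.DataFrame(rows),
        mixture=mixture,
        organ_factors={
            "organ_area_factor": scenario.organ_area_factor,
            "organ_width_factor": scenario.organ_width_factor,
            "cavity_area_factor": scenario.cavity_area_factor,
        },
        displacement=displacement,
    )
    return after, truth


def _ring_from_walls(walls: dict) -> np.ndarray:
    return np.vstack(
        [
            walls["inner"],
            walls["lateral_b"][1:],
            walls["outer"][::-1][1:],
            walls["lateral_a"][::-1][1:-1],
        ]
    )


# ---------------------------------------------------------------------------
# imaging imperfections


def rigid_jitter(
    geom: LandmarkGeometry, max_tilt_deg: float, seed: int
) -> tuple[LandmarkGeometry, SyntheticTruth]:
    """Random rotation (|tilt| <= max_tilt_deg <= 60) plus translation."""
    if not 0 <= max_tilt_deg <= _MAX_TILT_DEG:
        raise InputError(f"max_tilt_deg must lie in [0, {_MAX_TILT_DEG}]")
    rng = np.random.default_rng(seed)
    tilt = rng.uniform(-max_tilt_deg, max_tilt_deg)
    shift = rng.uniform(-25.0, 25.0, size=2)
    phi = np.deg2rad(tilt)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pts = geom.points @ rot.T + shift
    truth = SyntheticTruth(
        seed=seed,
        transform={"tilt_deg": float(tilt), "shift_um": shift.tolist()},
    )
    return geom.with_points(pts), truth


def _shared_noise(pts: np.ndarray, sigma: float, rng) -> np.ndarray:
    """One Gaussian draw per *physical* point.

    Wall junctions appear once per adjacent wall with identical
    coordinates; a tracker digitizes such a point once, so coincident
    duplicates receive the same perturbation (which also keeps cell
    polygons chained under noise).
    """
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    draw = rng.normal(0.0, sigma, size=uniq.shape)
    return pts + draw[inverse]


def add_landmark_noise(
    geom: LandmarkGeometry, sigma: float, seed: int
) -> LandmarkGeometry:
    """i.i.d. Gaussian perturbation per landmark coordinate (σ in µm).

    Coincident duplicate landmarks (shared wall junctions) move together;
    see :func:`_shared_noise`.
    """
    if sigma < 0:
        raise InputError("noise sigma must be >= 0")
    if sigma == 0:
        return geom.with_points(geom.points.copy())
    rng = np.random.default_rng(seed)
    return geom.with_points(_shared_noise(geom.points, sigma, rng))


# ---------------------------------------------------------------------------
# apex swelling and sperm tracks


def make_apex_series(
    scenario: BurstScenario, seed: Optional[int] = None
) -> tuple[list, np.ndarray, SyntheticTruth]:
    """Apex outer-wall series growing linearly to its burst maximum.

    Frames are sampled at ``frame_rate``; the wall's arc length grows
    linearly from L0 to L0*(1 + apex_growth) over ``apex_duration_s`` and
    the series ends at the maximum (the burst).  Returns
    ``(walls, times_s, truth)``.
    """
    ax_o = scenario.organ_basal_width_um / 2.0
    ay_o = scenario.organ_height_um / 2.0
    base = _ellipse_point(
        _apex_wall_phi(scenario), ax_o, ay_o, np.array([0.0, ay_o])
    )
    center = base.mean(axis=0)
    k_max = int(round(scenario.apex_duration_s * scenario.frame_rate))
    if k_max < 1:
        raise GenerationError("apex series needs at least two frames")
    times = np.arange(k_max + 1) / scenario.frame_rate
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    walls = []
    lengths = []
    for k in range(k_max + 1):
        f = 1.0 + scenario.apex_growth * k / k_max
        pts = center + f * (base - center)
        lengths.append(polyline_arclength(pts))
        if scenario.noise_sigma_um > 0:
            pts = pts + rng.normal(0.0, scenario.noise_sigma_um, size=pts.shape)
        walls.append(WallPolyline(pts, wall="", cell_id=""))
    truth = SyntheticTruth(
        seed=seed,
        apex_growth_percent=scenario.apex_growth * 100.0,
        apex_duration_s=float(times[-1]),
        apex_lengths=np.asarray(lengths),
    )
    return walls, times, truth


def _as_profile(profile, n_steps: int, name: str) -> np.ndarray:
    arr = np.asarray(profile, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_steps, float(arr))
    if arr.shape != (n_steps,):
        raise InputError(f"{name} must be a scalar or length-{n_steps} array")
    return arr


def make_sperm_mass_track(
    center_speed,
    radius_speed,
    duration_s: float,
    time_step: float,
    noise: float = 0.0,
    seed: int = 0,
    *,
    specimen_id: str = "mass",
    r0: float = 8.0,
) -> tuple[SpermMassTrack, SyntheticTruth]:
    """Integrate speed profiles into a tracked sperm-mass circle.

    ``center_speed`` (>= 0) and ``radius_speed`` may be scalars or
    per-step arrays (µm/s); the center advects along +x.  Gaussian noise
    of s.d. ``noise`` µm is added to centers and radii.
    """
    n_steps = int(round(duration_s / time_step))
    if n_steps < 1:
        raise InputError("track needs at least one step")
    cs = _as_profile(center_speed, n_steps, "center_speed")
    rs = _as_profile(radius_speed, n_steps, "radius_speed")
    if np.any(cs < 0):
        raise InputError("center_speed is a magnitude and must be >= 0")
    times = np.arange(n_steps + 1) * time_step
    xs = np.concatenate([[0.0], np.cumsum(cs) * time_step])
    radii = np.concatenate([[r0], r0 + np.cumsum(rs) * time_step])
    centers = np.column_stack([xs, np.zeros_like(xs)])
    if np.any(radii <= 0):
        raise GenerationError("radius profile drives the sperm-mass radius <= 0")
    if noise > 0:
        rng = np.random.default_rng(seed)
        centers = centers + rng.normal(0.0, noise, size=centers.shape)
        radii = radii + rng.normal(0.0, noise, size=radii.shape)
        if np.any(radii <= 0):
            raise GenerationError("noise drove the sperm-mass radius <= 0")
    track = SpermMassTrack(specimen_id, times, centers, radii)
    truth = SyntheticTruth(
        seed=seed, center_speeds=cs, radius_speeds=rs, end_speeds=cs + rs
    )
    return track, truth


def make_sperm_track(
    speed: float,
    heading_wobble_deg: float,
    duration_s: float,
    time_step: float,
    seed: int = 0,
    *,
    specimen_id: str = "sperm",
    substeps: int = 20,
) -> tuple[SpermTrack, SyntheticTruth]:
    """Individual sperm swimming at constant speed with a wandering heading.

    The heading performs a random walk of intensity
    ``heading_wobble_deg`` (degrees per sqrt-second) on a fine internal
    grid, so recorded inter-frame chords are slightly shorter than the
    swum path; with zero wobble the track is a straight line and the
    initial-speed estimate is exact.
    """
    if speed < 0:
        raise InputError("speed must be >= 0")
    n_steps = int(round(duration_s / time_step))
    if n_steps < 1:
        raise InputError("track needs at least one step")
    rng = np.random.default_rng(seed)
    dt_sub = time_step / substeps
    wobble = np.deg2rad(heading_wobble_deg)
    heading = 0.0
    pos = np.zeros(2)
    positions = [pos.copy()]
    for _ in range(n_steps):
        for _ in range(substeps):
            heading += wobble * np.sqrt(dt_sub) * rng.normal()
            pos = pos + speed * dt_sub * np.array([np.cos(heading), np.sin(heading)])
        positions.append(pos.copy())
    track = SpermTrack(
        specimen_id,
        np.arange(n_steps + 1) * time_step,
        np.asarray(positions),
        initial_index=0,
    )
    return track, SyntheticTruth(seed=seed, sperm_speed=float(speed))


# ---------------------------------------------------------------------------
# full dataset


def simulate_burst_dataset(
    scenario: BurstScenario, n_specimens: int, seed: int
) -> tuple[list, list]:
    """Generate before/after-burst specimen series with recorded truth.

    Each specimen shares the template shape, draws its own cell factors,
    is rigidly jittered (one imaging pose for both frames) and then gets
    independent landmark noise per frame.  Returns
    ``(list of 2-frame GeometrySeries, list of SyntheticTruth)``.
    """
    if n_specimens < 1:
        raise InputError("need at least one specimen")
    template = make_antheridium_template(scenario)
    quiet = replace(scenario, noise_sigma_um=0.0)
    root = np.random.SeedSequence(seed)
    series_list, truths = [], []
    for i, child in enumerate(root.spawn(n_specimens)):
        sub = np.random.default_rng(child)
        s_factors, s_jitter, s_nb, s_na = (
            int(x) for x in sub.integers(0, 2 ** 31, size=4)
        )
        sid = f"synth{i:03d}"
        before = template.geometry.with_points(
            template.geometry.points.copy(), specimen_id=sid
        )
        after, truth = apply_burst_deformation(template, quiet, s_factors)
        after = after.with_points(after.points, specimen_id=sid)
        jittered_before, jt = rigid_jitter(before, scenario.max_tilt_deg, s_jitter)
        rot_shift = jt.transform
        phi = np.deg2rad(rot_shift["tilt_deg"])
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        jittered_after = after.with_points(
            after.points @ rot.T + np.asarray(rot_shift["shift_um"])
        )
        noisy_before = add_landmark_noise(
            jittered_before, scenario.noise_sigma_um, s_nb
        )
        noisy_after = add_landmark_noise(
            jittered_after, scenario.noise_sigma_um, s_na
        )
        series_list.append(GeometrySeries(sid, [noisy_before, noisy_after]))
        truth.transform = rot_shift
        truth.extra["specimen_id"] = sid
        truths.append(truth)
    return series_list, truths
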