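"""CSV / JSON / YAML formats for landmarks, tracks, speeds and metrics.

All tables are comma-separated UTF-8 with a mandatory header, '.' decimal
and floats at 9 significant digits.  Coordinates are µm in a right-handed
plane, times in seconds; no pixel conversion happens here.

Landmark table columns (one row per landmark):
    specimen_id, frame, time_s, structure, cell_id, wall, point_index,
    x_um, y_um, anchor
``point_index`` counts within its (structure, cell_id, wall) group; the
groups of one frame must be contiguous and exactly one ``left`` and one
``right`` anchor must exist per (specimen_id, frame).  Reading preserves
the file's row order as the landmark order, so write -> read is an
identity and read -> write is byte-stable.

Track table columns: specimen_id, frame, time_s, kind (sperm_mass |
sperm), center_x_um, center_y_um, radius_um (empty for kind=sperm).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .geometry import (
    STRUCTURES,
    WALL_KINDS,
    GeometrySeries,
    LandmarkGeometry,
    NormalizationResult,
)
from .kinematics import SpermMassTrack, SpermTrack
from .synthetic import BurstScenario, SyntheticTruth

__all__ = [
    "LANDMARK_COLUMNS",
    "TRACK_COLUMNS",
    "read_landmarks",
    "write_landmarks",
    "read_tracks",
    "write_tracks",
    "write_speeds",
    "write_metrics",
    "write_transforms",
    "write_truths",
    "load_scenario",
]

LANDMARK_COLUMNS = [
    "specimen_id", "frame", "time_s", "structure", "cell_id", "wall",
    "point_index", "x_um", "y_um", "anchor",
]
TRACK_COLUMNS = [
    "specimen_id", "frame", "time_s", "kind",
    "center_x_um", "center_y_um", "radius_um",
]

_FLOAT_FMT = "%.9g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


def _fail(path, row, rule) -> None:
    where = f"{path}" if row is None else f"{path}, row {row}"
    raise ValidationError(f"{where}: {rule}")


def _read_table(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        _fail(path, None, "file has no header")
    if list(df.columns) != columns:
        _fail(path, None,
              f"header must be exactly {columns}, got {list(df.columns)}")
    return df


def _to_float(df, col, path):
    try:
        return df[col].astype(float).to_numpy()
    except ValueError:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        _fail(path, int(bad) + 2, f"column {col!r} is not numeric")


def _to_int(df, col, path):
    vals = _to_float(df, col, path)
    ints = vals.astype(int)
    if np.any(ints != vals):
        bad = int(np.flatnonzero(ints != vals)[0])
        _fail(path, bad + 2, f"column {col!r} must be integer")
    return ints


# ---------------------------------------------------------------------------
# landmarks


def write_landmarks(series: Sequence[GeometrySeries], path) -> None:
    """Write geometry series as the canonical landmark CSV."""
    rows = []
    for s in series:
        for g in s.frames:
            group_counter: dict = {}
            for i in range(g.n):
                key = (g.structure[i], g.cell_id[i], g.wall[i])
                idx = group_counter.get(key, 0)
                group_counter[key] = idx + 1
                anchor = ""
                if i == g.anchor_left:
                    anchor = "left"
                elif i == g.anchor_right:
                    anchor = "right"
                rows.append(
                    (
                        g.specimen_id, str(g.frame), _fmt(g.time_s),
                        g.structure[i], g.cell_id[i], g.wall[i], str(idx),
                        _fmt(g.points[i, 0]), _fmt(g.points[i, 1]), anchor,
                    )
                )
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmarks(path) -> list:
    """Read a landmark CSV into a list of GeometrySeries.

    Validation failures raise :class:`ValidationError` naming the file,
    row number (1-based, header = row 1) and the violated rule.
    """
    df = _read_table(path, LANDMARK_COLUMNS)
    if df.empty:
        return []
    frames_num = _to_int(df, "frame", path)
    times = _to_float(df, "time_s", path)
    xs = _to_float(df, "x_um", path)
    ys = _to_float(df, "y_um", path)
    pidx = _to_int(df, "point_index", path)
    for i, s in enumerate(df["structure"]):
        if s not in STRUCTURES:
            _fail(path, i + 2, f"unknown structure {s!r}")
    for i, w in enumerate(df["wall"]):
        if w not in ("",) + WALL_KINDS:
            _fail(path, i + 2, f"unknown wall {w!r}")
    for i, a in enumerate(df["anchor"]):
        if a not in ("", "left", "right"):
            _fail(path, i + 2, f"anchor must be left, right or empty, got {a!r}")
    key_cols = df[["specimen_id", "frame", "structure", "cell_id", "wall",
                   "point_index"]]
    dup = key_cols.duplicated()
    if dup.any():
        _fail(path, int(df.index[dup][0]) + 2,
              "duplicate (specimen_id, frame, structure, cell_id, wall, "
              "point_index) key")

    by_specimen: dict = {}
    work = df.assign(
        _frame=frames_num, _t=times, _x=xs, _y=ys, _pi=pidx, _row=df.index + 2
    )
    for (sid, frame), grp in work.groupby(
        ["specimen_id", "_frame"], sort=False
    ):
        # groups must be contiguous with point_index counting 0,1,... inside
        keys = list(zip(grp["structure"], grp["cell_id"], grp["wall"]))
        rows_ = grp["_row"].to_numpy()
        pis = grp["_pi"].to_numpy()
        seen_blocks: set = set()
        pos_in_block = 0
        for j, key in enumerate(keys):
            new_block = j == 0 or key != keys[j - 1]
            if new_block:
                if key in seen_blocks:
                    _fail(path, int(rows_[j]),
                          f"rows of group {key} are not contiguous")
                seen_blocks.add(key)
                pos_in_block = 0
            if int(pis[j]) != pos_in_block:
                _fail(path, int(rows_[j]),
                      f"point_index must count 0,1,... within group {key}")
            pos_in_block += 1
        anchors = {}
        for side in ("left", "right"):
            pos = np.flatnonzero(grp["anchor"].to_numpy() == side)
            if len(pos) != 1:
                _fail(path, int(grp["_row"].iloc[0]),
                      f"specimen {sid!r} frame {frame}: need exactly one "
                      f"{side} anchor, found {len(pos)}")
            anchors[side] = int(pos[0])
        t_vals = grp["_t"].to_numpy()
        if np.ptp(t_vals) != 0:
            _fail(path, int(grp["_row"].iloc[0]),
                  f"specimen {sid!r} frame {frame}: time_s must be constant "
                  "within a frame")
        geom = LandmarkGeometry(
            specimen_id=sid,
            frame=int(frame),
            time_s=float(t_vals[0]),
            points=np.column_stack([grp["_x"].to_numpy(), grp["_y"].to_numpy()]),
            structure=grp["structure"].to_numpy(dtype=object),
            cell_id=grp["cell_id"].to_numpy(dtype=object),
            wall=grp["wall"].to_numpy(dtype=object),
            anchor_left=anchors["left"],
            anchor_right=anchors["right"],
        )
        by_specimen.setdefault(sid, []).append(geom)
    out = []
    for sid in sorted(by_specimen):
        frames = sorted(by_specimen[sid], key=lambda g: g.frame)
        out.append(GeometrySeries(sid, frames))
    return out


# ---------------------------------------------------------------------------
# tracks


def write_tracks(
    mass_tracks: Sequence[SpermMassTrack],
    sperm_tracks: Sequence[SpermTrack],
    path,
) -> None:
    rows = []
    for tr in mass_tracks:
        for i in range(len(tr)):
            rows.append(
                (tr.specimen_id, str(i + 1), _fmt(tr.time_s[i]), "sperm_mass",
                 _fmt(tr.centers[i, 0]), _fmt(tr.centers[i, 1]),
                 _fmt(tr.radii[i]))
            )
    for tr in sperm_tracks:
        for i in range(len(tr.time_s)):
            rows.append(
                (tr.specimen_id, str(i + 1), _fmt(tr.time_s[i]), "sperm",
                 _fmt(tr.positions[i, 0]), _fmt(tr.positions[i, 1]), "")
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path) -> tuple:
    """Read a track CSV -> (sperm-mass tracks, individual sperm tracks)."""
    df = _read_table(path, TRACK_COLUMNS)
    if df.empty:
        return [], []
    _to_int(df, "frame", path)
    times = _to_float(df, "time_s", path)
    xs = _to_float(df, "center_x_um", path)
    ys = _to_float(df, "center_y_um", path)
    for i, k in enumerate(df["kind"]):
        if k not in ("sperm_mass", "sperm"):
            _fail(path, i + 2, f"kind must be sperm_mass or sperm, got {k!r}")
    radii = np.full(len(df), np.nan)
    is_mass = (df["kind"] == "sperm_mass").to_numpy()
    for i, raw in enumerate(df["radius_um"]):
        if is_mass[i]:
            if raw == "":
                _fail(path, i + 2, "sperm_mass rows need radius_um")
            r = float(raw)
            if r <= 0:
                _fail(path, i + 2, f"radius_um must be > 0, got {r}")
            radii[i] = r
        elif raw != "":
            _fail(path, i + 2, "sperm rows must leave radius_um empty")
    mass, sperm = [], []
    work = df.assign(_t=times, _x=xs, _y=ys, _r=radii)
    for (sid, kind), grp in work.groupby(["specimen_id", "kind"], sort=True):
        order = np.argsort(grp["_t"].to_numpy(), kind="stable")
        t = grp["_t"].to_numpy()[order]
        pts = np.column_stack([grp["_x"].to_numpy(), grp["_y"].to_numpy()])[order]
        if kind == "sperm_mass":
            mass.append(SpermMassTrack(sid, t, pts, grp["_r"].to_numpy()[order]))
        else:
            sperm.append(SpermTrack(sid, t, pts, initial_index=0))
    return mass, sperm


# ---------------------------------------------------------------------------
# derived tables and sidecars


def write_speeds(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_metrics(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_transforms(results: Sequence[NormalizationResult], path) -> None:
    """Per-specimen normalization sidecar JSON."""
    payload = [r.to_sidecar() for r in results]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_truths(truths: Sequence[SyntheticTruth], path) -> None:
    payload = [t.to_dict() for t in truths]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_scenario(path) -> BurstScenario:
    """Load a BurstScenario from YAML or JSON; unknown keys are errors."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        _fail(path, None, "scenario file must hold a mapping")
    valid = {f.name for f in dataclasses.fields(BurstScenario)}
    unknown = set(data) - valid
    if unknown:
        _fail(path, None, f"unknown scenario keys {sorted(unknown)}")
    return BurstScenario(**data)
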