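"""Ejected sperm-mass and individual-sperm kinematics.

The sperm mass expelled at antheridium burst is tracked as a circle per
frame: center (x, y) and radius r, both in µm.  Three per-step speeds
describe its motion between consecutive frames:

* ``center`` — Euclidean speed of the circle center,
  ||(x(t) - x(t-1), y(t) - y(t-1))|| / dt;
* ``radius`` — signed expansion rate (r(t) - r(t-1)) / dt;
* ``end``    — their sum, the speed of the leading edge of the mass.

Raw speeds are smoothed with a three-point mean filter (each step averaged
with its two neighbours); the filter is only evaluated where all three
samples exist, so the smoothed series drops one step at each end.
Individual sperm release speed is the displacement rate out of the tracked
initial point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "SpermMassTrack",
    "SpeedSeries",
    "SpermTrack",
    "raw_mass_speeds",
    "smooth_speeds",
    "initial_sperm_speed",
    "mass_speed_table",
]

_DT_TOL = 1e-6  # s, allowed jitter in the frame interval


@dataclass
class SpermMassTrack:
    """Tracked sperm-mass circle of one specimen (uniform frame interval)."""

    specimen_id: str
    time_s: np.ndarray
    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        s = len(self.time_s)
        if s < 2:
            raise InputError("a sperm-mass track needs at least 2 samples")
        if self.centers.shape != (s, 2) or self.radii.shape != (s,):
            raise InputError("track arrays must share the sample count")
        if np.any(self.radii <= 0.0):
            raise InputError(
                f"specimen {self.specimen_id!r}: sperm-mass radii must be positive"
            )
        steps = np.diff(self.time_s)
        if np.any(steps <= 0.0):
            raise InputError("track times must be strictly increasing")
        if np.ptp(steps) > _DT_TOL:
            raise InputError(
                f"specimen {self.specimen_id!r}: non-uniform time step "
                f"(spread {np.ptp(steps):.3g} s exceeds {_DT_TOL} s)"
            )

    @property
    def time_step(self) -> float:
        return float(np.mean(np.diff(self.time_s)))

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class SpeedSeries:
    """Per-step speeds of one sperm-mass track (µm/s).

    ``steps`` holds the 1-based sample index t each speed belongs to
    (the step from sample t-1 to sample t); ``kind`` is "raw" or
    "smoothed".  ``end == center + radius`` at every step.
    """

    specimen_id: str
    steps: np.ndarray
    time_s: np.ndarray
    center: np.ndarray
    radius: np.ndarray
    end: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        for name in ("steps", "time_s", "center", "radius", "end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.steps = self.steps.astype(int)
        n = len(self.steps)
        for name in ("time_s", "center", "radius", "end"):
            if len(getattr(self, name)) != n:
                raise InputError("speed series arrays must share one length")
        if self.kind not in ("raw", "smoothed"):
            raise InputError(f"unknown speed series kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class SpermTrack:
    """Positions of one individual sperm over time."""

    specimen_id: str
    time_s: np.ndarray
    positions: np.ndarray
    initial_index: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        s = len(self.time_s)
        if s < 2:
            raise InputError("a sperm track needs at least 2 samples")
        if self.positions.shape != (s, 2):
            raise InputError("positions must be an (n, 2) array matching time_s")
        if np.any(np.diff(self.time_s) <= 0.0):
            raise InputError("track times must be strictly increasing")
        if not 0 <= self.initial_index < s:
            raise InputError(f"initial_index {self.initial_index} outside track")


def raw_mass_speeds(track: SpermMassTrack) -> SpeedSeries:
    """Per-step raw center / radius / end speeds of a sperm-mass track."""
    dt = track.time_step
    disp = np.diff(track.centers, axis=0)
    center = np.hypot(disp[:, 0], disp[:, 1]) / dt
    radius = np.diff(track.radii) / dt
    return SpeedSeries(
        specimen_id=track.specimen_id,
        steps=np.arange(1, len(track)),
        time_s=track.time_s[1:],
        center=center,
        radius=radius,
        end=center + radius,
        kind="raw",
    )


def _mean3(values: np.ndarray) -> np.ndarray:
    return np.convolve(values, np.ones(3) / 3.0, mode="valid")


def smooth_speeds(raw: SpeedSeries) -> SpeedSeries:
    """Three-point mean filter applied to every speed channel.

    Each interior step becomes the average of itself and its two
    neighbouring steps; the two boundary steps are dropped because the
    filter is undefined there.  Needs at least 3 raw steps.
    """
    if raw.kind != "raw":
        raise InputError("smooth_speeds expects a raw speed series")
    if len(raw) < 3:
        raise InputError("smoothing needs at least 3 raw steps")
    return SpeedSeries(
        specimen_id=raw.specimen_id,
        steps=raw.steps[1:-1],
        time_s=raw.time_s[1:-1],
        center=_mean3(raw.center),
        radius=_mean3(raw.radius),
        end=_mean3(raw.end),
        kind="smoothed",
    )


def initial_sperm_speed(track: SpermTrack) -> float:
    """Release speed of an individual sperm (µm/s).

    Displacement from the tracked initial point to the next sample,
    divided by the time gap between them.
    """
    i = track.initial_index
    if i + 1 >= len(track.time_s):
        raise InputError("initial point is the last sample; no successor")
    disp = track.positions[i + 1] - track.positions[i]
    return float(np.hypot(*disp) / (track.time_s[i + 1] - track.time_s[i]))


def mass_speed_table(track: SpermMassTrack) -> pd.DataFrame:
    """Tidy per-step speed table with raw and smoothed channels.

    Columns: specimen_id, step, time_s, channel, raw_um_per_s,
    smoothed_um_per_s (NaN where the filter is undefined).
    """
    raw = raw_mass_speeds(track)
    smoothed = smooth_speeds(raw) if len(raw) >= 3 else None
    rows = []
    for channel in ("center", "radius", "end"):
        rvals = getattr(raw, channel)
        svals = np.full(len(raw), np.nan)
        if smoothed is not None:
            svals[1:-1] = getattr(smoothed, channel)
        for step, t, rv, sv in zip(raw.steps, raw.time_s, rvals, svals):
            rows.append(
                {
                    "specimen_id": track.specimen_id,
                    "step": int(step),
                    "time_s": float(t),
                    "channel": channel,
                    "raw_um_per_s": float(rv),
                    "smoothed_um_per_s": float(sv),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["specimen_id", "step", "time_s", "channel",
                 "raw_um_per_s", "smoothed_um_per_s"],
    )
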