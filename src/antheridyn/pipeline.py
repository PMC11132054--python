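"""End-to-end analysis helpers chaining normalization and morphometrics.

These are the entry points the command line uses and the ones a notebook
user typically wants: register every specimen, measure the before/after
burst metrics, and summarize them across a dataset.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .exceptions import InputError
from .geometry import (
    GeometrySeries,
    burst_dynamics,
    displacement_stats,
    mean_shape,
    normalize_series,
)
from .morphometrics import METRIC_COLUMNS, burst_metrics

__all__ = [
    "analyze_burst_series",
    "dataset_metrics",
    "summarize_metrics",
    "dataset_dynamics",
]


def analyze_burst_series(series: GeometrySeries):
    """Normalize one 2-frame series and measure its burst metrics.

    Returns ``(metric table, normalization result)``; the first frame is
    the pre-burst and the last frame the post-burst configuration.
    """
    if len(series) < 2:
        raise InputError(
            f"specimen {series.specimen_id!r}: need a before and an after frame"
        )
    normalized, result = normalize_series(series)
    table = burst_metrics(normalized.frames[0], normalized.frames[-1])
    return table, result


def dataset_metrics(series_list: Sequence[GeometrySeries]) -> pd.DataFrame:
    """Per-cell and organ metrics for every specimen, one tidy table."""
    tables = []
    for series in series_list:
        table, _ = analyze_burst_series(series)
        tables.append(table)
    if not tables:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean, s.d. and count of every metric across the dataset."""
    g = metrics.groupby(["metric", "units"], sort=True)["value"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out[["metric", "units", "n", "mean", "sd"]]


def dataset_dynamics(series_list: Sequence[GeometrySeries]):
    """Mean shapes before/after burst and their deformation field.

    Normalizes every series, averages the first frames into the pre-burst
    geometry model and the last frames into the post-burst model, and
    returns ``(before model, after model, deformation field, per-wall
    displacement statistics of the cell landmarks)``.
    """
    before_frames, after_frames = [], []
    for series in series_list:
        normalized, _ = normalize_series(series)
        before_frames.append(normalized.frames[0])
        after_frames.append(normalized.frames[-1])
    before = mean_shape(before_frames)
    after = mean_shape(after_frames)
    field = burst_dynamics(before, after)
    cell_sel = before.structure == "cell"
    stats = displacement_stats(
        type(field)(field.vectors[cell_sel]), before.wall[cell_sel]
    )
    return before, after, field, stats
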