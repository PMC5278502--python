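"""Trace normalization and heatmap construction.

Intensity time courses are reported relative to the first acquired frame
(t = 0), so every normalized trace starts at exactly 1. Heatmaps show one
cell per row, rows ordered by the cell's highest normalized intensity
within the first 24 h (ties broken by cell_id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import QCError, Trace


def normalize_to_start(trace: Trace) -> Trace:
    """Divide a trace by its value at the first frame.

    The first value of the output is exactly 1. Idempotent. A non-positive
    starting value makes the fold-change undefined; such traces are
    rejected with :class:`QCError` so callers can log the exclusion.
    """
    first = trace.intensity[0]
    if not np.isfinite(first) or first <= 0:
        raise QCError("nonpositive_start",
                      f"{trace.cell_id}: first intensity {first} is not > 0")
    return trace.with_intensity(trace.intensity / first)


@dataclass(frozen=True)
class HeatmapMatrix:
    """Row-ordered matrix of normalized single-cell time courses.

    ``values`` has one row per cell (index: cell_id, ordered) and one
    column per sampling time. ``row_order_key`` is each cell's max
    normalized intensity within the ordering window. ``clipped`` marks
    entries above the display ceiling (rendered as saturated colour),
    if a ceiling was given.
    """

    values: pd.DataFrame
    row_order_key: pd.Series
    window_hr: float
    ceiling: float | None = None

    @property
    def clipped(self) -> pd.DataFrame:
        if self.ceiling is None:
            return self.values != self.values  # all False
        return self.values > self.ceiling


def build_heatmap(traces: list[Trace], window_hr: float = 24.0,
                  ceiling: float | None = None) -> HeatmapMatrix:
    """Assemble the per-cell heatmap from a set of traces.

    Traces must share one sampling grid (resampling is out of scope here).
    Each trace is normalized to its first frame; rows are sorted by
    descending maximum normalized intensity over [0, window_hr], ties
    broken by cell_id, so the result is a pure function of the trace set.
    """
    if not traces:
        raise ValueError("no traces")
    grid = traces[0].time_hr
    for tr in traces[1:]:
        if len(tr) != len(grid) or not np.allclose(tr.time_hr, grid):
            raise ValueError("traces have mixed sampling grids")
    normed = [normalize_to_start(tr) for tr in traces]
    mat = pd.DataFrame({tr.cell_id: tr.intensity for tr in normed},
                       index=grid).T
    mat.index.name = "cell_id"
    mat.columns.name = "time_hr"
    in_window = grid <= window_hr
    key = mat.loc[:, in_window].max(axis=1)
    order = sorted(mat.index, key=lambda cid: (-key[cid], cid))
    mat = mat.loc[order]
    return HeatmapMatrix(values=mat, row_order_key=key.loc[order],
                         window_hr=window_hr, ceiling=ceiling)
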