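"""Core single-cell trace container and CSV interchange.

A :class:`Trace` is one cell's fluorescence intensity time series together
with the metadata the downstream stages key on: a cell identifier, the
clock-neuron class (e.g. ``LNv``, ``DN1``, ``DN2``), and the treatment
group. Times are in hours from the start of imaging; intensities are in
arbitrary fluorescence units (AU).

Collections of traces travel between pipeline stages as long-format CSV
with columns ``cell_id, neuron_class, group, time_hr, intensity``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["cell_id", "neuron_class", "group", "time_hr", "intensity"]


class QCError(ValueError):
    """A trace failed a quality-control precondition.

    Carries a short machine-readable ``reason`` (e.g. ``"nonpositive_start"``)
    so callers can log exclusions rather than crash.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


@dataclass(frozen=True)
class Trace:
    """One cell's intensity time series.

    Parameters
    ----------
    cell_id : str
        Unique cell identifier.
    neuron_class : str
        Clock-neuron class label.
    group : str
        Treatment group label ("+"-joined treatments, e.g. ``"PDF+TTX"``).
    time_hr : ndarray
        Strictly increasing sampling times in hours.
    intensity : ndarray
        Fluorescence intensity (AU) at each time, same length as ``time_hr``.
    """

    cell_id: str
    neuron_class: str
    group: str
    time_hr: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_hr, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time_hr", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("time_hr and intensity must be 1-D and equal length")
        if len(t) < 2:
            raise ValueError("a trace needs at least 2 timepoints")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite sampling times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_hr)

    @property
    def sampling_interval_hr(self) -> float:
        """Median sampling step in hours."""
        return float(np.median(np.diff(self.time_hr)))

    def with_intensity(self, intensity: np.ndarray) -> "Trace":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Stack traces into a long-format DataFrame (one row per timepoint)."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "neuron_class": tr.neuron_class,
                    "group": tr.group,
                    "time_hr": tr.time_hr,
                    "intensity": tr.intensity,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(parts, ignore_index=True)[TRACE_COLUMNS]


def frame_to_traces(df: pd.DataFrame) -> list[Trace]:
    """Rebuild :class:`Trace` objects from a long-format table.

    Rows are sorted by time within each cell; cells come back in sorted
    cell_id order so the result is independent of row order on disk.
    """
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("time_hr")
        traces.append(
            Trace(
                cell_id=str(cell_id),
                neuron_class=str(sub["neuron_class"].iloc[0]),
                group=str(sub["group"].iloc[0]),
                time_hr=sub["time_hr"].to_numpy(dtype=float),
                intensity=sub["intensity"].to_numpy(dtype=float),
            )
        )
    return traces


def read_traces_csv(path) -> list[Trace]:
    return frame_to_traces(pd.read_csv(path))


def write_traces_csv(traces: list[Trace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.10g")
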