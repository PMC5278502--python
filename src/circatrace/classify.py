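"""Dual-criterion circadian rhythmicity calls and cohort summaries.

A cell is scored *circadian* only when both independent criteria agree:

1. **trend criterion** — the degree-6 polynomial trend shows at least one
   peak-to-peak interval of 18-36 h (:mod:`circatrace.trend`);
2. **MESA criterion** — the Burg AR spectrum has a dominant period inside
   18-36 h (:mod:`circatrace.mesa`).

The reported period is always the MESA period; the trend only gates the
call. Cells failing quality control (too short, non-positive first frame,
non-finite values) are recorded as non-circadian with QC flags and can be
excluded from cohort denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mesa, trend
from .trace import QCError, Trace

DEFAULT_BAND_HR = (18.0, 36.0)


@dataclass(frozen=True)
class RhythmConfig:
    """Knobs of the rhythmicity pipeline (all defaults are the standard run)."""

    band_hr: tuple[float, float] = DEFAULT_BAND_HR
    order_rule: object = "n/3"
    n_frequencies: int = mesa.DEFAULT_N_FREQUENCIES
    min_points: int = 8
    exclude_qc_failures_from_denominator: bool = True


@dataclass(frozen=True)
class RhythmCall:
    """Per-cell classification record."""

    cell_id: str
    neuron_class: str
    trend_circadian: bool
    mesa_period_hr: float | None
    mesa_in_band: bool
    is_circadian: bool
    qc_flags: frozenset = frozenset()


def classify_cell(trace: Trace, config: RhythmConfig = RhythmConfig()) -> RhythmCall:
    """Apply both criteria to one trace and take their conjunction.

    MESA runs on the raw (un-normalized) intensities; the trend criterion
    is scale-invariant so it also runs on the raw series. QC failures
    yield a non-circadian call carrying the failure reasons.
    """
    flags = set()
    if len(trace) < config.min_points:
        flags.add("too_short")
    if not np.all(np.isfinite(trace.intensity)):
        flags.add("nonfinite_values")
    if trace.intensity[0] <= 0:
        flags.add("nonpositive_start")
    if flags:
        return RhythmCall(cell_id=trace.cell_id, neuron_class=trace.neuron_class,
                          trend_circadian=False, mesa_period_hr=None,
                          mesa_in_band=False, is_circadian=False,
                          qc_flags=frozenset(flags))

    try:
        fit = trend.fit_trend(trace)
        intervals = trend.peak_to_peak_intervals(fit)
        trend_ok = trend.trend_is_circadian(intervals, config.band_hr)
    except QCError as err:
        flags.add(err.reason)
        trend_ok = False

    period = mesa.estimate_period(
        trace.intensity, trace.sampling_interval_hr,
        order_rule=config.order_rule, band_hr=config.band_hr,
        n_frequencies=config.n_frequencies,
    )
    in_band = period is not None
    return RhythmCall(cell_id=trace.cell_id, neuron_class=trace.neuron_class,
                      trend_circadian=trend_ok, mesa_period_hr=period,
                      mesa_in_band=in_band,
                      is_circadian=trend_ok and in_band,
                      qc_flags=frozenset(flags))


def classify_cohort(traces: list[Trace],
                    config: RhythmConfig = RhythmConfig()) -> list[RhythmCall]:
    return [classify_cell(tr, config) for tr in traces]


@dataclass(frozen=True)
class CohortSummary:
    """Per-neuron-class rhythmicity summary.

    ``fraction_rhythmic = n_rhythmic / n_detected``; mean and SEM of the
    MESA period are over rhythmic cells only (SEM = sample sd / sqrt(n),
    None when fewer than 1 / 2 rhythmic cells respectively).
    """

    neuron_class: str
    n_detected: int
    n_rhythmic: int
    fraction_rhythmic: float
    mean_period_hr: float | None
    sem_period_hr: float | None


def summarize_cohort(calls: list[RhythmCall],
                     config: RhythmConfig = RhythmConfig()) -> list[CohortSummary]:
    """Summarize calls per neuron class.

    "Detected" cells are those passing QC (QC failures are dropped from
    the denominator when the config says so, mirroring how undetectable
    cells are absent from reported fractions).
    """
    out = []
    by_class: dict[str, list[RhythmCall]] = {}
    for c in calls:
        if config.exclude_qc_failures_from_denominator and c.qc_flags:
            continue
        by_class.setdefault(c.neuron_class, []).append(c)
    for ncls in sorted(by_class):
        group = by_class[ncls]
        rhythmic = [c for c in group if c.is_circadian]
        periods = np.array([c.mesa_period_hr for c in rhythmic], dtype=float)
        if len(periods) == 0:
            mean = sem = None
        else:
            mean = round(float(periods.mean()), 2)
            sem = (round(float(periods.std(ddof=1) / np.sqrt(len(periods))), 2)
                   if len(periods) > 1 else None)
        out.append(CohortSummary(
            neuron_class=ncls, n_detected=len(group), n_rhythmic=len(rhythmic),
            fraction_rhythmic=len(rhythmic) / len(group),
            mean_period_hr=mean, sem_period_hr=sem,
        ))
    return out


def calls_to_frame(calls: list[RhythmCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": c.cell_id, "neuron_class": c.neuron_class,
        "trend_circadian": c.trend_circadian,
        "mesa_period_hr": (np.nan if c.mesa_period_hr is None
                           else round(c.mesa_period_hr, 2)),
        "mesa_in_band": c.mesa_in_band, "is_circadian": c.is_circadian,
        "qc_flags": ";".join(sorted(c.qc_flags)),
    } for c in calls])


def summaries_to_frame(summaries: list[CohortSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "neuron_class": s.neuron_class, "n_detected": s.n_detected,
        "n_rhythmic": s.n_rhythmic, "fraction_rhythmic": s.fraction_rhythmic,
        "mean_period_hr": np.nan if s.mean_period_hr is None else s.mean_period_hr,
        "sem_period_hr": np.nan if s.sem_period_hr is None else s.sem_period_hr,
    } for s in summaries])
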