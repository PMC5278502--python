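"""Polynomial-trend rhythmicity criterion.

Manual rhythm inspection of short fluorescence time courses is commonly
aided by superimposing a 6th-order polynomial trend line and checking
whether successive trend peaks are a circadian interval apart. This module
makes that procedure reproducible: an ordinary least-squares degree-6 fit
(on a shifted/scaled abscissa for conditioning), interior trend maxima
located as roots of the fitted polynomial's derivative, and a boolean
criterion — circadian iff at least one peak-to-peak interval falls within
[18, 36] h inclusive.

The trend criterion only ever contributes a yes/no; the period itself is
always taken from the spectral (MESA) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import QCError, Trace

TREND_DEGREE = 6
MIN_POINTS = 8
DEFAULT_BAND_HR = (18.0, 36.0)


@dataclass(frozen=True)
class TrendFit:
    """Degree-6 OLS trend of one trace.

    ``coefficients`` are in the plain power basis (time in hours,
    ascending degree); the internal domain-scaled polynomial is kept for
    numerically stable evaluation and root finding. Peaks are strictly
    interior local maxima of the fitted curve within the observed window.
    """

    coefficients: np.ndarray  # length 7, ascending powers of t (hours)
    fitted_values: np.ndarray
    peak_times_hr: np.ndarray
    window_hr: tuple[float, float]
    _poly: object = None  # numpy Polynomial in scaled domain

    def __call__(self, t):
        return self._poly(np.asarray(t, dtype=float))


def fit_trend(trace: Trace) -> TrendFit:
    """Least-squares degree-6 polynomial trend of a trace.

    Requires at least 8 timepoints (7 coefficients); shorter traces raise
    :class:`QCError` and the trend criterion is simply not applied to
    them. Exactly reproduces any polynomial of degree <= 6 present in the
    data.
    """
    if len(trace) < MIN_POINTS:
        raise QCError("too_short_for_trend",
                      f"{trace.cell_id}: {len(trace)} < {MIN_POINTS} points")
    t, y = trace.time_hr, trace.intensity
    poly = np.polynomial.Polynomial.fit(t, y, deg=TREND_DEGREE)
    fitted = poly(t)
    # a numerically flat trend has no meaningful extrema (round-off can
    # produce spurious derivative roots on constant data)
    scale = max(1.0, float(np.abs(fitted).max()))
    if float(fitted.max() - fitted.min()) <= 1e-9 * scale:
        peaks = np.array([])
    else:
        peaks = _interior_maxima(poly, t[0], t[-1])
    return TrendFit(coefficients=poly.convert().coef,
                    fitted_values=fitted,
                    peak_times_hr=peaks,
                    window_hr=(float(t[0]), float(t[-1])),
                    _poly=poly)


def _interior_maxima(poly, t_first: float, t_last: float) -> np.ndarray:
    """Strictly interior local maxima via derivative root-finding.

    Roots of p' with negative p'' (or, at degenerate critical points, a
    +/- sign change of p' across the root) count as maxima. Endpoint
    extrema are excluded: an interval to an unobserved peak cannot be
    measured.
    """
    d1 = poly.deriv()
    d2 = d1.deriv()
    roots = d1.roots()
    real = roots[np.abs(roots.imag) < 1e-8].real
    span = t_last - t_first
    eps = 1e-9 * max(span, 1.0)
    inside = real[(real > t_first + eps) & (real < t_last - eps)]
    maxima = []
    for r in np.sort(inside):
        curv = d2(r)
        if curv < 0:
            maxima.append(r)
        elif curv == 0:
            h = 1e-6 * span
            if d1(r - h) > 0 > d1(r + h):
                maxima.append(r)
    # merge numerically duplicated roots
    out = []
    for r in maxima:
        if not out or r - out[-1] > 1e-6 * span:
            out.append(float(r))
    return np.array(out)


def peak_to_peak_intervals(fit: TrendFit) -> list[float]:
    """Hours between consecutive interior trend peaks ([] if < 2 peaks)."""
    if len(fit.peak_times_hr) < 2:
        return []
    return [float(d) for d in np.diff(fit.peak_times_hr)]


def trend_is_circadian(intervals: list[float],
                       band_hr: tuple[float, float] = DEFAULT_BAND_HR) -> bool:
    """True iff at least one peak-to-peak interval lies in the band.

    Band endpoints are inclusive ("from 18 to 36 hr").
    """
    lo, hi = band_hr
    return any(lo <= iv <= hi for iv in intervals)
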