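"""Maximum Entropy Spectral Analysis (MESA) for short circadian series.

MESA estimates a power spectrum by fitting an autoregressive (AR) model
with Burg's method, which minimizes the combined forward and backward
prediction error order-recursively. Unlike the raw periodogram, the AR
spectrum of a short record (here typically 15-20 frames spanning two
circadian cycles) is smooth and can resolve a dominant period without
windowing or padding, which is why it is the standard choice for rhythm
detection in short or noisy circadian recordings.

The pipeline entry point is :func:`estimate_period`: mean-centre the raw
series (no detrending, no smoothing), fit an AR model, evaluate its
spectrum on a fine frequency grid, and pick the highest in-band spectral
local maximum, refined by parabolic interpolation on log-power. The
circadian search band defaults to periods of 18-36 h.

Conventions
-----------
AR coefficients use the prediction form ``x_t ~ sum_k a_k x_{t-k}``; the
spectral density of an order-p model is::

    P(f) = sigma2 * dt / |1 - sum_k a_k exp(-i 2 pi f k dt)|^2

on f in (0, Nyquist], with sigma2 the innovation variance and dt the
sampling interval in hours (f in cycles/hour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_BAND_HR = (18.0, 36.0)
DEFAULT_N_FREQUENCIES = 2048
MAX_DEFAULT_ORDER = 20


@dataclass(frozen=True)
class ARModel:
    """Fitted AR model (prediction convention x_t ~ sum a_k x_{t-k})."""

    order: int
    coefficients: np.ndarray  # length p
    innovation_variance: float  # AU^2
    sampling_interval_hr: float
    reflection_coefficients: np.ndarray  # length p, all in [-1, 1]
    zero_variance: bool = False  # constant input series

    def __post_init__(self):
        object.__setattr__(self, "coefficients",
                           np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "reflection_coefficients",
                           np.asarray(self.reflection_coefficients, dtype=float))
        if self.innovation_variance < 0:
            raise ValueError("innovation_variance must be >= 0")


@dataclass(frozen=True)
class SpectralEstimate:
    """Evaluated AR power spectrum with its dominant circadian period."""

    frequency_grid: np.ndarray  # cycles/hour, uniform over (0, Nyquist]
    power: np.ndarray  # AU^2 * hour
    sampling_interval_hr: float
    dominant_period_hr: float | None = None
    search_band_hr: tuple[float, float] = DEFAULT_BAND_HR


def _taper_weights(length: int, taper: str | None) -> np.ndarray:
    if taper is None or taper == "none":
        return np.ones(length)
    i = np.arange(length)
    u = (i - (length - 1) / 2.0) / ((length + 1) / 2.0)
    if taper == "parabolic":
        return 1.0 - u * u
    if taper == "hamming":
        return np.hamming(length + 2)[1:-1]
    raise ValueError(f"unknown taper: {taper!r}")


def burg_fit(series, order: int, sampling_interval_hr: float = 1.0,
             taper: str | None = "parabolic") -> ARModel:
    """Fit an AR model by Burg's recursion.

    The series is mean-centred internally. Reflection coefficients are
    bounded by 1 in magnitude (Cauchy-Schwarz), which guarantees a stable
    model and a positive spectrum. A constant series yields a
    zero-variance model flagged via ``zero_variance``.

    By default each stage's reflection coefficient is computed with a
    parabolic taper on the forward/backward error products (the optimum
    taper of the windowed-Burg literature). Plain Burg exhibits a strong
    phase-dependent frequency bias on records spanning only ~1-2 cycles —
    for a clean 29 h cosine sampled every 3 h over 48 h the spectral peak
    can be off by over 2.5 h depending on starting phase; the taper
    reduces that worst-case bias to ~0.3 h. ``taper=None`` gives the
    classic recursion.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if order < 0:
        raise ValueError("order must be >= 0")
    n = len(x)
    if order >= n:
        raise ValueError(f"order {order} must be < series length {n}")
    x = x - x.mean()
    E = float(np.dot(x, x) / n)
    if E == 0.0:
        return ARModel(order=order, coefficients=np.zeros(order),
                       innovation_variance=0.0,
                       sampling_interval_hr=sampling_interval_hr,
                       reflection_coefficients=np.zeros(order),
                       zero_variance=True)
    if order == 0:
        return ARModel(order=0, coefficients=np.zeros(0),
                       innovation_variance=E,
                       sampling_interval_hr=sampling_interval_hr,
                       reflection_coefficients=np.zeros(0))

    # ef[t] / eb[t]: forward / backward prediction errors; arrays shrink by
    # one sample per stage as the prediction window loses an endpoint.
    ef = x[1:].copy()
    eb = x[:-1].copy()
    a = np.zeros(0)  # polynomial convention: x_t + sum a'_k x_{t-k} = e_t
    ks = []
    for _ in range(order):
        w = _taper_weights(len(ef), taper)
        den = float(np.dot(w, ef * ef) + np.dot(w, eb * eb))
        if den == 0.0:
            k = 0.0
        else:
            k = float(-2.0 * np.dot(w, ef * eb) / den)
            k = float(np.clip(k, -1.0, 1.0))
        ks.append(k)
        a = np.append(a + k * a[::-1], k)
        E *= (1.0 - k * k)
        ef_new = ef + k * eb
        eb_new = eb + k * ef
        ef = ef_new[1:]
        eb = eb_new[:-1]
    return ARModel(order=order, coefficients=-a, innovation_variance=max(E, 0.0),
                   sampling_interval_hr=sampling_interval_hr,
                   reflection_coefficients=np.array(ks))


def evaluate_spectrum(model: ARModel, n_frequencies: int = DEFAULT_N_FREQUENCIES,
                      band_hr: tuple[float, float] = DEFAULT_BAND_HR) -> SpectralEstimate:
    """Evaluate the AR power spectrum on a uniform grid over (0, Nyquist]."""
    if n_frequencies < 64:
        raise ValueError("n_frequencies must be >= 64")
    dt = model.sampling_interval_hr
    nyquist = 0.5 / dt
    freqs = nyquist * np.arange(1, n_frequencies + 1) / n_frequencies
    if model.order == 0:
        power = np.full_like(freqs, model.innovation_variance * dt)
    else:
        k = np.arange(1, model.order + 1)
        # denominator 1 - sum a_k exp(-i 2 pi f k dt)
        phase = np.exp(-2j * np.pi * np.outer(freqs * dt, k))
        denom = 1.0 - phase @ model.coefficients
        denom2 = np.maximum(np.abs(denom) ** 2, np.finfo(float).tiny)
        power = model.innovation_variance * dt / denom2
    return SpectralEstimate(frequency_grid=freqs, power=power,
                            sampling_interval_hr=dt, search_band_hr=band_hr)


def _parabolic_refine(freqs: np.ndarray, logp: np.ndarray, i: int) -> float:
    """Vertex of the parabola through (i-1, i, i+1) in log-power."""
    denom = logp[i - 1] - 2.0 * logp[i] + logp[i + 1]
    if denom >= 0:  # not locally concave; keep grid point
        return float(freqs[i])
    delta = 0.5 * (logp[i - 1] - logp[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    df = freqs[1] - freqs[0]
    return float(freqs[i] + delta * df)


def dominant_period(estimate: SpectralEstimate,
                    band_hr: tuple[float, float] = DEFAULT_BAND_HR) -> float | None:
    """Period of the highest spectral local maximum within the band.

    Local maxima are interior grid points that strictly dominate both
    neighbours; only maxima whose period 1/f lies in ``band_hr`` count.
    The winning peak's frequency is refined by parabolic interpolation on
    log-power; ties in power are broken toward the longest period.
    Returns None when no in-band local maximum exists (e.g. a flat or
    monotone spectrum).
    """
    lo, hi = band_hr
    if not (0 < lo < hi):
        raise ValueError("need 0 < band low < band high")
    p = estimate.power
    f = estimate.frequency_grid
    if np.allclose(p, p[0]):
        return None
    interior = np.arange(1, len(p) - 1)
    is_max = (p[interior] > p[interior - 1]) & (p[interior] > p[interior + 1])
    peaks = interior[is_max]
    with np.errstate(divide="ignore"):
        periods = 1.0 / f[peaks]
    in_band = peaks[(periods >= lo) & (periods <= hi)]
    if len(in_band) == 0:
        return None
    # highest power wins; among equals prefer the lowest frequency
    # (longest period) — deterministic tie-break
    best_power = p[in_band].max()
    candidates = in_band[p[in_band] >= best_power * (1.0 - 1e-12)]
    i = int(candidates.min())
    logp = np.log(np.maximum(p, np.finfo(float).tiny))
    f_star = _parabolic_refine(f, logp, i)
    period = 1.0 / f_star
    return float(min(max(period, lo), hi))


def resolve_order(n: int, order_rule="n/3") -> int:
    """Translate an order rule into a concrete AR order for n samples.

    ``"n/3"`` (default): floor(n/3) capped at 20 — conventional for short
    circadian records, keeping roughly two observations per parameter at
    n ~ 16-20. An integer is used as-is; a callable receives n.
    """
    if callable(order_rule):
        order = int(order_rule(n))
    elif isinstance(order_rule, int):
        order = order_rule
    elif order_rule == "n/3":
        order = min(n // 3, MAX_DEFAULT_ORDER)
    elif order_rule == "aic":
        return -1  # sentinel: select by AIC
    else:
        raise ValueError(f"unknown order rule: {order_rule!r}")
    return max(1, min(order, n - 1))


def _select_order_aic(x: np.ndarray, dt: float,
                      taper: str | None = "parabolic") -> ARModel:
    """Fit orders 1..min(n/2, 20) and keep the AIC minimizer."""
    n = len(x)
    best = None
    best_aic = math.inf
    for p in range(1, min(n // 2, MAX_DEFAULT_ORDER) + 1):
        m = burg_fit(x, p, dt, taper=taper)
        if m.innovation_variance <= 0:
            continue
        aic = n * math.log(m.innovation_variance) + 2 * p
        if aic < best_aic:
            best_aic, best = aic, m
    return best if best is not None else burg_fit(x, 1, dt, taper=taper)


def estimate_period(series, sampling_interval_hr: float,
                    order_rule="n/3",
                    band_hr: tuple[float, float] = DEFAULT_BAND_HR,
                    n_frequencies: int = DEFAULT_N_FREQUENCIES,
                    taper: str | None = "parabolic") -> float | None:
    """Full MESA period estimate for one series.

    Mean-centre -> Burg fit -> AR spectrum -> dominant in-band period.
    No detrending or smoothing is applied. Series shorter than 8 points
    return None (too short for a meaningful fit), as do series whose
    spectrum has no local maximum with period inside ``band_hr`` — note a
    recording much shorter than the band's period floor (e.g. an 8-h drug
    run against an 18-h floor) cannot yield an in-band peak.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 8:
        return None
    if order_rule == "aic":
        model = _select_order_aic(x, sampling_interval_hr, taper=taper)
    else:
        order = resolve_order(len(x), order_rule)
        model = burg_fit(x, order, sampling_interval_hr, taper=taper)
    if model.zero_variance:
        return None
    est = evaluate_spectrum(model, n_frequencies=n_frequencies, band_hr=band_hr)
    return dominant_period(est, band_hr)
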