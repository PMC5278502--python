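"""Synthetic single-cell circadian data with known ground truth.

The generators here emulate the data regimes of larval-brain fluorescent
clock-reporter experiments:

* **Explant-like traces** — sampled every 3 h for >= 48 h, damped ~29 h
  oscillations on a slowly drifting baseline (rhythmic cells), or a
  monotone rise with no oscillation (non-rhythmic cells, as seen in
  dissociated neuron cultures).
* **Drug-response experiments** — short hourly recordings (baseline then
  8 h) where a bath-applied drug produces a step or ramp increase in the
  reporter of specific (treatment group, neuron class) strata, optionally
  blocked by a co-treatment such as TTX.
* **3-D image stacks** — spherical-Gaussian "cells" over a background with
  an optional linear gradient and noise, whose integrated intensities
  follow supplied traces.

Every generator takes an explicit integer seed and is bitwise reproducible.
Ground truth (rhythmic flags, true periods, per-cell integrated
intensities) is always returned beside the data so downstream accuracy can
be scored without peeking.

The rhythmic trace model is a damped cosine on a multiplicative linear
drift::

    I(t) = [mesor + amplitude * exp(-damping_rate*t) * cos(2*pi*(t - phase_hr)/period_hr)]
           * (1 + drift_rate*t) + eps(t),   eps ~ N(0, noise_sd**2), truncated at 0

which is the minimal form exhibiting every phenomenon the analysis stages
must handle (long period, amplitude damping, baseline drift, noise,
non-negativity of fluorescence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .trace import Trace

__all__ = [
    "TraceModelParams",
    "DrugEffectSpec",
    "StackSpec",
    "BlobSpec",
    "generate_trace",
    "generate_cohort",
    "generate_response_experiment",
    "render_stack_series",
    "gaussian_blob_mass_above",
    "EXPLANT_COHORT_DEFAULTS",
]


@dataclass(frozen=True)
class TraceModelParams:
    """Parameters of the damped-cosine-with-drift trace model.

    All intensities are in arbitrary units (AU), all times in hours.

    mesor : rhythm midline level (AU)
    amplitude : initial oscillation amplitude (AU); 0 = non-rhythmic
    period_hr : oscillation period (h), must be > 0
    phase_hr : time of the first cosine maximum (h)
    damping_rate : exponential amplitude decay, per hour, >= 0
    drift_rate : fractional baseline drift per hour (multiplicative)
    noise_sd : additive Gaussian noise s.d. (AU), >= 0
    sampling_interval_hr : time between frames (h)
    duration_hr : total recording span (h), >= sampling_interval_hr
    """

    mesor: float = 100.0
    amplitude: float = 50.0
    period_hr: float = 29.0
    phase_hr: float = 0.0
    damping_rate: float = 0.01
    drift_rate: float = 0.0
    noise_sd: float = 10.0
    sampling_interval_hr: float = 3.0
    duration_hr: float = 48.0

    def validate(self) -> None:
        vals = [
            self.mesor, self.amplitude, self.period_hr, self.phase_hr,
            self.damping_rate, self.drift_rate, self.noise_sd,
            self.sampling_interval_hr, self.duration_hr,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite trace model parameter")
        if self.period_hr <= 0:
            raise ValueError("period_hr must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.damping_rate < 0:
            raise ValueError("damping_rate must be >= 0")
        if self.sampling_interval_hr <= 0:
            raise ValueError("sampling_interval_hr must be > 0")
        if self.duration_hr < self.sampling_interval_hr:
            raise ValueError("duration_hr must be >= sampling_interval_hr")

    @property
    def n_timepoints(self) -> int:
        return int(math.floor(self.duration_hr / self.sampling_interval_hr)) + 1

    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.sampling_interval_hr

    def mean_signal(self, t: np.ndarray) -> np.ndarray:
        """Noise-free model mean at times ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        osc = self.amplitude * np.exp(-self.damping_rate * t) * np.cos(
            2.0 * np.pi * (t - self.phase_hr) / self.period_hr
        )
        return (self.mesor + osc) * (1.0 + self.drift_rate * t)


def generate_trace(
    params: TraceModelParams,
    seed: int,
    cell_id: str = "cell",
    neuron_class: str = "LNv",
    group: str = "Vehicle",
) -> Trace:
    """Draw one trace from the model; identical seed => identical trace."""
    params.validate()
    rng = np.random.default_rng(seed)
    t = params.times()
    y = params.mean_signal(t)
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=t.shape)
    y = np.maximum(y, 0.0)  # fluorescence is non-negative
    return Trace(cell_id=cell_id, neuron_class=neuron_class, group=group,
                 time_hr=t, intensity=y)


# Default per-parameter uniform ranges for explant-like cohorts. The study
# conditions these emulate: ~29 h periods (we draw 27-31 h), 3 h sampling
# over 48 h, visible damping, mild baseline drift, and noise at roughly
# amplitude/5 (SNR ~5). Non-rhythmic cells get amplitude 0 and a clearly
# positive drift (steady monotone rise).
EXPLANT_COHORT_DEFAULTS: dict[str, tuple[float, float]] = {
    "mesor": (80.0, 120.0),
    "amplitude": (40.0, 60.0),
    "period_hr": (27.0, 31.0),
    "phase_hr": (0.0, 29.0),
    "damping_rate": (0.005, 0.02),
    "drift_rate": (-0.002, 0.002),
    "noise_sd": (8.0, 12.0),
    "nonrhythmic_drift_rate": (0.01, 0.03),
}


def _allocate_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items to labelled proportions."""
    labels = sorted(proportions)
    exact = {lab: n * proportions[lab] for lab in labels}
    counts = {lab: int(math.floor(exact[lab])) for lab in labels}
    short = n - sum(counts.values())
    # hand leftovers to largest fractional remainders; ties by label order
    order = sorted(labels, key=lambda lab: (-(exact[lab] - counts[lab]), lab))
    for lab in order[:short]:
        counts[lab] += 1
    return counts


def generate_cohort(
    n_cells: int,
    class_mix: dict[str, float] | None = None,
    rhythmic_fraction: float = 0.6,
    params_distribution: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    sampling_interval_hr: float = 3.0,
    duration_hr: float = 48.0,
) -> tuple[list[Trace], pd.DataFrame]:
    """Generate a cohort of explant-like traces with ground-truth labels.

    Exactly ``round(n_cells * rhythmic_fraction)`` cells are rhythmic
    (deterministic assignment). Non-rhythmic cells have amplitude 0 and a
    positive drift. Per-cell parameters are drawn uniformly from
    ``params_distribution`` ranges (defaults:
    :data:`EXPLANT_COHORT_DEFAULTS`).

    Returns
    -------
    traces : list of Trace
    ground_truth : DataFrame with columns
        ``cell_id, neuron_class, is_rhythmic, true_period_hr``
        (period is NaN for non-rhythmic cells).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= rhythmic_fraction <= 1.0:
        raise ValueError("rhythmic_fraction must be in [0, 1]")
    class_mix = class_mix or {"LNv": 0.4, "DN1": 0.35, "DN2": 0.25}
    if any(not 0.0 <= p <= 1.0 for p in class_mix.values()):
        raise ValueError("class proportions must be in [0, 1]")
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    dist = dict(EXPLANT_COHORT_DEFAULTS)
    if params_distribution:
        dist.update(params_distribution)

    rng = np.random.default_rng(seed)
    class_counts = _allocate_counts(n_cells, class_mix)
    classes = [lab for lab in sorted(class_counts) for _ in range(class_counts[lab])]
    n_rhythmic = int(round(n_cells * rhythmic_fraction))
    flags = np.zeros(n_cells, dtype=bool)
    flags[rng.permutation(n_cells)[:n_rhythmic]] = True

    def draw(name: str) -> float:
        lo, hi = dist[name]
        return float(rng.uniform(lo, hi))

    traces: list[Trace] = []
    gt_rows = []
    width = len(str(n_cells - 1))
    for i in range(n_cells):
        cid = f"cell{i:0{width}d}"
        if flags[i]:
            params = TraceModelParams(
                mesor=draw("mesor"), amplitude=draw("amplitude"),
                period_hr=draw("period_hr"), phase_hr=draw("phase_hr"),
                damping_rate=draw("damping_rate"), drift_rate=draw("drift_rate"),
                noise_sd=draw("noise_sd"),
                sampling_interval_hr=sampling_interval_hr, duration_hr=duration_hr,
            )
            true_period = params.period_hr
        else:
            params = TraceModelParams(
                mesor=draw("mesor"), amplitude=0.0,
                period_hr=29.0, phase_hr=0.0, damping_rate=0.0,
                drift_rate=draw("nonrhythmic_drift_rate"),
                noise_sd=draw("noise_sd"),
                sampling_interval_hr=sampling_interval_hr, duration_hr=duration_hr,
            )
            true_period = float("nan")
        child_seed = int(rng.integers(0, 2**31 - 1))
        traces.append(generate_trace(params, seed=child_seed, cell_id=cid,
                                     neuron_class=classes[i], group="explant"))
        gt_rows.append({"cell_id": cid, "neuron_class": classes[i],
                        "is_rhythmic": bool(flags[i]),
                        "true_period_hr": true_period})
    return traces, pd.DataFrame(gt_rows)


# ---------------------------------------------------------------------------
# Drug-response experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugEffectSpec:
    """Ground-truth effect of a bath-applied drug.

    A treatment *group* label is a "+"-joined set of treatments
    (e.g. ``"PDF+TTX"``). A (group, class) stratum gains the effect after
    ``onset_hr`` iff the group contains at least one treatment in
    ``affected_groups``, contains none in ``blocked_by``, and the class is
    in ``affected_classes``.

    effect_shape : ``"step"`` (constant fold-increase after onset) or
        ``"ramp"`` (fold-increase growing linearly after onset).
    effect_size : fractional increase — total for a step, per-hour for a
        ramp. Effects are multiplicative on the normalized (fold-change)
        scale.
    """

    onset_hr: float = 1.0
    affected_groups: frozenset = frozenset({"PDF"})
    affected_classes: frozenset = frozenset({"LNv", "DN1"})
    effect_shape: str = "ramp"
    effect_size: float = 0.1
    blocked_by: frozenset = frozenset({"TTX"})

    def validate(self, duration_hr: float) -> None:
        if not math.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if not 0.0 <= self.onset_hr <= duration_hr:
            raise ValueError("onset_hr outside recording window")
        if self.effect_shape not in ("step", "ramp"):
            raise ValueError("effect_shape must be 'step' or 'ramp'")

    def fold_factor(self, t: np.ndarray, group: str, neuron_class: str) -> np.ndarray:
        """Multiplicative effect factor at times t for one stratum."""
        t = np.asarray(t, dtype=float)
        treatments = set(group.split("+"))
        hit = bool(treatments & set(self.affected_groups))
        blocked = bool(treatments & set(self.blocked_by))
        if not hit or blocked or neuron_class not in self.affected_classes:
            return np.ones_like(t)
        after = np.clip(t - self.onset_hr, 0.0, None)
        if self.effect_shape == "step":
            return 1.0 + self.effect_size * (t >= self.onset_hr)
        return 1.0 + self.effect_size * after


def generate_response_experiment(
    spec: DrugEffectSpec,
    groups: list[str] = ("Vehicle", "PDF"),
    classes: list[str] = ("LNv", "DN1", "DN2"),
    n_per_group_class: int = 30,
    baseline_hr: float = 1.0,
    duration_hr: float = 8.0,
    sampling_interval_hr: float = 1.0,
    seed: int = 0,
    mesor_range: tuple[float, float] = (80.0, 120.0),
    noise_cv: float = 0.08,
) -> pd.DataFrame:
    """Simulate an hourly drug-response experiment.

    Each cell is flat-plus-noise before drug onset; affected strata then
    gain the spec's multiplicative effect. ``noise_cv`` is the per-frame
    noise s.d. as a fraction of the cell's baseline level.

    Returns a long-format table with columns
    ``cell_id, neuron_class, group, time_hr, intensity``.
    """
    if baseline_hr >= duration_hr:
        raise ValueError("baseline_hr must be < duration_hr")
    spec.validate(duration_hr)
    known = set().union(*(set(g.split("+")) for g in groups))
    unknown = (set(spec.affected_groups) | set(spec.blocked_by)) - known
    # blocked_by co-treatments may legitimately be absent from this run's
    # groups, but affected treatments must exist somewhere
    if set(spec.affected_groups) - known:
        raise ValueError(f"affected_groups not present in groups: {sorted(set(spec.affected_groups) - known)}")
    if set(spec.affected_classes) - set(classes):
        raise ValueError("affected_classes not present in classes")

    rng = np.random.default_rng(seed)
    n_t = int(math.floor(duration_hr / sampling_interval_hr)) + 1
    t = np.arange(n_t) * sampling_interval_hr
    rows = []
    idx = 0
    for group in groups:
        for ncls in classes:
            factor = spec.fold_factor(t, group, ncls)
            for _ in range(n_per_group_class):
                mesor = rng.uniform(*mesor_range)
                y = mesor * factor + rng.normal(0.0, noise_cv * mesor, size=n_t)
                y = np.maximum(y, 0.0)
                rows.append(pd.DataFrame({
                    "cell_id": f"c{idx:04d}", "neuron_class": ncls,
                    "group": group, "time_hr": t, "intensity": y,
                }))
                idx += 1
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# 3-D image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobSpec:
    """One spherical-Gaussian cell in a stack."""

    center: tuple[float, float, float]  # (z, y, x), voxels
    radius_voxels: float  # Gaussian sigma, voxels
    peak_intensity: float  # AU above background at t=0
    neuron_class: str = "LNv"


@dataclass(frozen=True)
class StackSpec:
    """Geometry of a synthetic image stack.

    shape : (z, y, x) voxel counts
    cells : list of :class:`BlobSpec`
    background_level : constant background (AU)
    background_gradient : AU per voxel added along the x axis
    noise_model : ``"none"``, ``("gaussian", sd)`` or ``"poisson"``
    """

    shape: tuple[int, int, int] = (16, 48, 48)
    cells: tuple = ()
    background_level: float = 10.0
    background_gradient: float = 0.0
    noise_model: object = "none"

    def validate(self) -> None:
        nz, ny, nx = self.shape
        for c in self.cells:
            cz, cy, cx = c.center
            if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
                raise ValueError(f"cell center {c.center} outside volume {self.shape}")
            if c.peak_intensity <= max(self.background_level, 0.0):
                raise ValueError("peak_intensity must exceed background_level")
            if c.radius_voxels <= 0:
                raise ValueError("radius_voxels must be > 0")


def _blob_field(shape: tuple[int, int, int], blob: BlobSpec) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = blob.center
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    return np.exp(-d2 / (2.0 * blob.radius_voxels**2))


def gaussian_blob_mass_above(total_mass: float, peak: float, threshold: float) -> float:
    """Analytic mass of a 3-D Gaussian blob above an intensity threshold.

    For a blob ``peak * exp(-r^2 / 2 sigma^2)`` with integral ``total_mass``,
    the integral over the region where intensity > ``threshold`` is
    ``total_mass * P(3/2, ln(peak / threshold))`` with P the regularized
    lower incomplete gamma function. Used as the independent ground truth
    for thresholded 3-D mask sums.
    """
    if threshold >= peak:
        return 0.0
    u = math.log(peak / threshold)
    return float(total_mass * special.gammainc(1.5, u))


def render_stack_series(
    spec: StackSpec,
    trace_per_cell: list[Trace],
    seed: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render a time series of 3-D volumes from blob specs and traces.

    Each cell's blob at timepoint k is scaled so its *integrated* (summed)
    intensity is proportional to that cell's trace value:
    ``peak_intensity * trace[k] / trace[0]`` sets the blob peak above
    background. Ground truth records, per cell and timepoint, the exact
    rendered integral, the blob peak, sigma and an overlap flag.

    Returns
    -------
    volumes : list of float64 arrays, one (z, y, x) volume per timepoint
    ground_truth : DataFrame with columns ``cell_id, time_hr, peak,
        sigma_voxels, true_integral, overlaps``
    """
    spec.validate()
    if len(trace_per_cell) != len(spec.cells):
        raise ValueError("need exactly one trace per cell in spec")
    if spec.cells:
        t0 = trace_per_cell[0].time_hr
        for tr in trace_per_cell[1:]:
            if len(tr) != len(t0) or not np.allclose(tr.time_hr, t0):
                raise ValueError("all traces must share one sampling grid")
        times = t0
    else:
        times = np.array([0.0])

    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    fields = [_blob_field(spec.shape, c) for c in spec.cells]

    # pairwise overlap: supports (3 sigma) intersect
    overlaps = [False] * len(spec.cells)
    for i in range(len(spec.cells)):
        for j in range(i + 1, len(spec.cells)):
            ci, cj = spec.cells[i], spec.cells[j]
            d = math.dist(ci.center, cj.center)
            if d < 3.0 * (ci.radius_voxels + cj.radius_voxels):
                overlaps[i] = overlaps[j] = True

    xgrad = np.arange(nx, dtype=float) * spec.background_gradient
    background = spec.background_level + xgrad[None, None, :]
    background = np.broadcast_to(background, spec.shape)

    volumes = []
    gt_rows = []
    width = max(1, len(str(max(len(spec.cells) - 1, 0))))
    for k, t in enumerate(times):
        vol = np.array(background, dtype=np.float64, copy=True)
        for i, (blob, fld) in enumerate(zip(spec.cells, fields)):
            tr = trace_per_cell[i]
            scale = tr.intensity[k] / tr.intensity[0] if tr.intensity[0] != 0 else 0.0
            peak = blob.peak_intensity * scale
            contrib = peak * fld
            vol += contrib
            gt_rows.append({
                "cell_id": f"blob{i:0{width}d}", "time_hr": float(t),
                "peak": float(peak), "sigma_voxels": blob.radius_voxels,
                "true_integral": float(contrib.sum()),
                "overlaps": overlaps[i],
            })
        if spec.noise_model == "poisson":
            vol = rng.poisson(np.maximum(vol, 0.0)).astype(np.float64)
        elif isinstance(spec.noise_model, tuple) and spec.noise_model[0] == "gaussian":
            vol = vol + rng.normal(0.0, spec.noise_model[1], size=vol.shape)
        elif spec.noise_model != "none":
            raise ValueError(f"unknown noise model: {spec.noise_model!r}")
        volumes.append(vol)
    return volumes, pd.DataFrame(gt_rows)
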