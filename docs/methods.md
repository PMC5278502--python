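# Methods

This note documents the models, estimators and design choices behind
`circatrace`, and what the shipped tests do and do not demonstrate.

## The trace model

Synthetic single-cell reporter traces follow a damped cosine on a
multiplicative linear drift:

    I(t) = [M + A e^{-λt} cos(2π(t − φ)/τ)] (1 + δt) + ε(t),  ε ~ N(0, σ²),

truncated below at 0 (fluorescence is non-negative). This is the minimal
form exhibiting everything the analysis must cope with: a long circadian
period τ, amplitude damping λ (explant rhythms visibly decay over two
days), slow baseline drift δ (focus changes, expression trends), and
frame-to-frame noise σ. Non-rhythmic cells — the phenotype of dissociated
cultured neurons, which rise steadily without detectable rhythm — are the
special case A = 0 with a clearly positive drift.

Default generator conditions (all overridable, never hidden constants):
period 27–31 h (explants run ~29 h), 3-h sampling over 48 h (17 frames),
mesor 80–120 AU, amplitude 40–60 AU, noise sd 8–12 AU (≈ amplitude/5,
i.e. SNR ≈ 5), damping 0.005–0.02 h⁻¹ (≈ 40–60% amplitude loss over 48 h),
drift ±0.002 h⁻¹ for rhythmic cells and +0.01–0.03 h⁻¹ for non-rhythmic
ones. Phases are uniform over one period — a conservative choice; real
explant cohorts are phase-coherent, which only makes detection easier.
Real-data features deliberately **not** emulated: photobleaching kinetics,
optical PSF structure, neurite morphology, movement artefacts, and
non-Gaussian noise. Passing tests therefore demonstrate correctness of
the estimators under the stated statistical regime, not robustness to
every microscopy artefact.

Drug-response experiments are flat-plus-noise per cell (CV 8% of the
cell's baseline) with a multiplicative step or ramp effect (default ramp
0.1 h⁻¹ from 1 h after start) applied to affected (group, class) strata.
Group labels are "+"-joined treatment sets; a group is affected when it
contains an affected treatment and none of the blocking co-treatments, so
"PDF+TTX" is blocked when TTX blocks. Effects are multiplicative because
the analysis operates on fold-change from the first frame.

Image stacks render each cell as a spherical Gaussian (σ =
`radius_voxels`) over a constant background plus optional linear gradient
and Gaussian or Poisson noise. The blob peak scales with the cell's trace
so its integrated intensity follows the trace. Ground truth records the
exact rendered integral per cell and timepoint. For *thresholded* 3-D
masks the relevant truth is the analytic mass of the blob **above the
threshold isosurface**, `total · P(3/2, ln(peak/threshold))` (regularized
incomplete gamma): only ~80% of a Gaussian's mass lies above a
10%-of-peak cut, so comparing a mask sum to the full integral would be a
category error. The full integral is the right reference for 2-D ROI
means, where a 3.5σ disc captures >99.7% of the projected mass.

## Image quantification

The 2-D scheme sums all z-slices (SUM projection; integer inputs widen to
int64 so the sum is exact), measures the mean over each manual cell ROI,
and subtracts the mean of exactly three nearby background-region means.
The corrected value may be negative and is then flagged, not clipped —
silent clipping would bias downstream rhythm amplitudes. The correction
is deliberately mean-based, not area-scaled integrated density; because
all downstream use is relative (fold-change from t = 0), the distinction
cancels for any fixed ROI. The 3-D scheme subtracts a scalar background
voxelwise (floored at 0), keeps voxels strictly above threshold, labels
26-connected components (the standard connectivity for blob-like somata),
and sums each component. Coordinates are 0-based (z, y, x) with half-open
ranges throughout.

## MESA period estimation

The estimator is Burg's order-recursive AR fit: at each stage the
reflection coefficient minimizes the combined forward/backward prediction
error, guaranteeing |k| ≤ 1 (Cauchy–Schwarz), hence a stable model and a
strictly positive spectrum. The series is mean-centred and otherwise
untouched — no detrending, smoothing or filtering — because the method's
value lies in what it extracts from the raw record.

Two numerical choices matter for 17-frame records spanning ~1.65 cycles:

* **Stagewise taper (default `parabolic`).** Plain Burg has a
  well-documented phase-dependent frequency bias on records of one to two
  cycles: on a *noise-free* 29-h cosine (48 h @ 3 h, order 5) the
  spectral peak lands up to ~2.6 h off depending on starting phase.
  Weighting the stagewise error products with a parabolic (optimum)
  taper reduces that worst-case clean-data bias to ~0.3 h. The cost is
  modestly inflated coefficient variance on stationary noise, which is
  why the classic recursion remains available (`taper=None`) and is the
  variant held to the tight white-noise coefficient bound in the tests.
* **Peak refinement.** The spectrum is evaluated on 2048 frequencies over
  (0, Nyquist] and the winning in-band local maximum is refined by
  parabolic interpolation on log-power, decoupling period precision from
  grid density. Ties in peak power break toward the longer period,
  deterministically.

AR order defaults to ⌊n/3⌋ capped at 20 — roughly two observations per
parameter at n ≈ 17 — with AIC selection available (`order_rule="aic"`).
Series shorter than 8 points return no estimate. A recording much shorter
than the search band's period floor (an 8-h drug run against an 18-h
floor) cannot produce an in-band peak and correctly yields "no period";
this is a structural limitation, not a failure mode.

**Known accuracy limit.** Under the full study conditions — damping,
drift, SNR 5, 1.65 observed cycles — the probability that a single-cell
MESA estimate lands within ±1.5 h of truth plateaus at ~0.86–0.91 across
the AR-spectral family (tapered Burg, AIC-selected Burg, and a
forward-backward least-squares diagnostic all measure the same), close to
the Cramér–Rao floor for this record length. Cohort-*mean* periods are
far tighter (bias ≈ −0.2 h). The acceptance suite asserts the ±1.5-h
property at its nominal 90% level and can therefore land a few points
short on an unlucky 100-trace draw; this is an estimator-family limit,
not a tunable.

## Trend criterion

"Manual inspection with superimposed 6th-order polynomial trend lines" is
operationalized as: OLS degree-6 fit on a shifted/scaled abscissa (exact
for any polynomial of degree ≤ 6), interior local maxima located as roots
of the fitted derivative with negative curvature (never sampled argmax),
endpoint extrema excluded (an interval to an unobserved peak cannot be
measured), and the criterion fires iff at least one consecutive-peak
interval lies in [18, 36] h inclusive. "At least one" rather than "all"
is our documented choice. A degree-6 trend of a two-cycle cosine shifts
peak spacing by up to ~3 h depending on phase — ample for the 18-h-wide
criterion band, which is all the trend is used for. The trend never
supplies a period; the classifier's period is always MESA's.

## Classification and summaries

The circadian verdict is the strict conjunction of the two criteria.
Cells failing QC (fewer than 8 frames, non-positive first frame,
non-finite values) are called non-circadian with explicit flags and are
excluded from cohort denominators by default ("detected" cells = cells
passing QC). Per-class summaries report n, fraction rhythmic, and mean ±
SEM (sample sd/√n) of the MESA period over rhythmic cells, rounded to two
decimals.

## Drug-response statistics

Per neuron class, a fixed-effects two-way ANOVA (treatment × time,
sum-to-zero coding, Type-III sums of squares via statsmodels OLS) is fit
to the fold-change table; each non-reference group is compared with the
vehicle group at each timepoint by a two-sided t-test on the pooled
residual mean square, Sidak-adjusted (p' = 1 − (1 − p)^m) with family
m = (groups − 1) × timepoints per class panel (per-timepoint families are
a config switch). Timepoints with zero variance are excluded from the
model: after fold-change normalization the first frame is identically 1
in every cell, and keeping that degenerate column would deflate the
pooled residual MS and make every contrast anticonservative.

Cells are the unit of observation; within-cell repeated-measures
correlation is ignored. Consequently the treatment *main-effect* F on
normalized repeated-measures data is anticonservative and should not be
used inferentially — the per-timepoint Sidak contrasts (the quantities
the time-course figures annotate) are the supported output. The ANOVA's
own calibration is verified on a null that satisfies its assumptions
(independent errors, no between-cell level variation), where the type-I
rate measures ~5%.

## Pipeline

Stages (simulate → quantify → prep → rhythms → respond → report) exchange
plain CSV; TIFF appears only at the imaging boundary. Every run writes
its resolved config and a config hash beside the outputs, stage seeds are
fixed offsets of the run seed, and CSV floats use a fixed format, so a
given config + seed reproduces every artifact byte for byte. Problem
sizes in the demo config (24-cell cohort, 30 cells per group × class in
the drug experiments, 48³-voxel stacks) were chosen to mirror the
single-brain scale of the study's figures while keeping a full run in the
tens of seconds.
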