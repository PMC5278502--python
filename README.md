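# circatrace

Single-cell fluorescence circadian analysis for clock-reporter imaging of
*Drosophila* pacemaker neurons (and similar preparations): quantify
reporter intensity per neuron from time-lapse confocal stacks, normalize
the time courses, estimate each cell's free-running period by Maximum
Entropy Spectral Analysis (MESA), call cells circadian by a dual
criterion, and test acute drug responses with two-way ANOVA and
Sidak-corrected per-timepoint comparisons.

It is aimed at chronobiologists working with short, noisy single-cell
recordings — brain-explant movies sampled every 3 h for ~2 days, or 8-h
hourly pharmacology runs — where standard periodogram methods lack the
resolution to say anything useful.

## What it computes

**Image quantification.** Two schemes mirror common practice:
a SUM z-projection with manual 2-D cell ROIs and exactly three nearby
background regions (corrected intensity = ROI mean − mean of the three
background means), and 3-D masks built by thresholding after voxelwise
background subtraction, summing the intensity in each 26-connected
component.

**MESA period estimation.** For a series \(x_t\) sampled at interval
\(\Delta t\), an AR(p) model \(x_t \approx \sum_{k=1}^{p} a_k x_{t-k}\) is
fit by Burg's order-recursion (tapered variant; see `docs/methods.md`) and
its spectral density

\[ P(f) = \frac{\sigma^2 \Delta t}{\left|1 - \sum_k a_k e^{-2\pi i f k \Delta t}\right|^2} \]

is evaluated on a fine grid; the dominant circadian period is the highest
spectral local maximum with period in the 18–36 h search band, refined by
parabolic interpolation.

**Rhythmicity call.** A cell is circadian only when *both* (i) its
degree-6 polynomial trend shows a peak-to-peak interval inside 18–36 h and
(ii) MESA finds a dominant period inside 18–36 h. The reported period is
always the MESA period.

**Drug-response statistics.** Per neuron class, normalized (fold-change)
intensities are analysed by fixed-effects two-way ANOVA
(treatment × time); each group is compared with the vehicle group at every
timepoint using the pooled residual variance, Sidak-corrected over the
panel's family of comparisons, with the usual `*`/`**`/`***`/`****` tiers.

A first-class synthetic-data module generates traces, cohorts, drug
experiments and 3-D image stacks with known ground truth, so every stage
can be scored quantitatively.

## Worked example

```python
import numpy as np
from circatrace import TraceModelParams, generate_trace, classify_cell

params = TraceModelParams(period_hr=29.0, amplitude=50.0, mesor=100.0,
                          damping_rate=0.01, noise_sd=10.0,
                          sampling_interval_hr=3.0, duration_hr=48.0)
trace = generate_trace(params, seed=7)
call = classify_cell(trace)
print(call.is_circadian, call.mesa_period_hr, call.trend_circadian)
```

prints

```
True 28.898061213033348 True
```

— the cell is called circadian: the MESA period (28.90 h) is within 0.2 h
of the generating 29 h despite SNR 5, 17 frames and visible damping, and
the polynomial trend independently shows an in-band peak-to-peak interval.

The full pipeline runs from a YAML config:

```bash
circatrace run --config examples/demo.yaml --out runs/demo
```

which simulates a 24-cell explant cohort, a three-group drug experiment
and a small image-stack series, then quantifies, normalizes, classifies
and tests them, writing CSV artifacts (per-cell calls, per-class
summaries with mean period ± SEM, Sidak-adjusted comparison tables), a
row-ordered heatmap, and the resolved config + hash for provenance.
Identical config and seed reproduce every output byte for byte. The
stage-level subcommands `simulate`, `quantify`, `rhythms`, `respond` and
`report` expose the same steps individually.

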