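# Methods

## Respiratory waveform model

Each trace is a uniformly sampled (default 30 Hz) three-direction position
signal. Per direction *d*,

    position_d(t) = baseline_d(t) + sign_d · A_{k,d} · s(φ(t)) + ε(t)

with `s(φ) = ((1 − cos 2πφ)/2)^p`. The default shape (`p = 1`) is a raised
cosine: continuous, analytically tractable, with well-separated extrema;
`p > 1` sharpens the troughs for breathing that dwells at expiration. The
cycle phase φ advances by one per breathing cycle; cycle *k* draws its
peak-to-peak amplitude `A_k ~ Normal(base, cv·base)` clipped at 0 and its
period `T_k ~ Normal(base, cv·base)` clipped at 0.2·base (the clipping
prevents non-physical negative amplitudes and collapsed cycles and is fully
seed-determined). Inspiration is the positive extreme; the expiration
trough sits exactly on the baseline, which makes drift-parameter recovery
well defined. ε is white Gaussian noise.

The baseline integrates a per-direction drift rate that is either constant
or piecewise linear. Key parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `base_amplitude_mm` | (4.0, 10.1, 2.5) | peak-to-peak AP/CC/LR, mm; CC dominates in lung targets |
| `base_period_s` | 3.0 | mean breathing cycle, s |
| `drift_rate_mm_per_s` | (0, 0, 0) | baseline slope per direction, mm/s |
| `amplitude_cv`, `period_cv` | 0 | per-cycle coefficient of variation |
| `noise_sd_mm` | 0 | tracking noise, mm |
| `sample_rate_hz` | 30 | typical of marker-tracking systems |

## Synthetic cohort

The default study cohort is 148 beams over 10 patients. Per-patient
dominant amplitude, cycle length, beam duration and beam count follow the
published characteristics of a gated lung-SBRT population (amplitudes
6.4–14.0 mm, cycles 2.1–4.7 s, beam times ≈122–185 s); each beam redraws
its own values from the patient's distribution. Each patient carries a
lung-lobe class that fixes the range of its per-beam CC drift-rate
magnitudes — upper lobe 0.03–0.13 mm/s, middle 0.06–0.30 mm/s, lower
0.30–0.74 mm/s — reflecting the clinical observation that lower-lobe
targets drift most. AP and LR amplitudes and drifts scale off CC (0.40/0.25
for amplitude, 0.54/0.50 for drift), matching the reported per-direction
drift ranges.

A constant 0.74 mm/s slope sustained over a 150 s beam would move the
target ~11 cm, which no lung tumour does; clinically the *per-cycle* slope
can be that large while the baseline wanders. The cohort therefore builds
the baseline from piecewise-linear segments (10–20 s long) whose slope
magnitude is the drawn per-beam rate and whose sign occasionally flips,
reflecting whenever the excursion would exceed ±8 mm. Per-beam mean Δ then
recovers the drawn magnitude while net travel stays realistic.

What the generator does **not** emulate: cardiac motion and coughing,
inter-direction hysteresis, surrogate-vs-marker mismatch, irregular apnoea,
or non-stationary amplitude trends. Tests passing on this cohort show the
pipeline's arithmetic and its qualitative drift/gating behaviour; they do
not certify performance on any individual patient's breathing pattern.

## Drift quantification

Expiration points are local minima (under the inspiration-positive sign
convention; a per-direction sign flag handles inverted axes) subject to

* spacing ≥ `min_period_s` (default half the autocorrelation-estimated
  cycle), and
* prominence ≥ 0.3 × the oscillation range.

The oscillation range is the peak-to-peak of the signal after removing a
one-cycle moving average. A raw global range would be inflated by the very
drift being measured (a 0.3 mm/s drift over 100 s adds 30 mm) and would
mask every trough on shallow-breathing beams, so the floor is computed on
the baseline-removed signal; on a stationary waveform the two are
identical.

On noisy data each expiration point can be refined by a least-squares
quadratic fit over a symmetric ±0.2 T window around the detected minimum
(`refine_half_width_s="auto"`). The fit averages the noise down by roughly
√n while the waveform's residual quartic term biases every cycle's vertex
equally and cancels in the consecutive differences that Δ uses. Without
the refinement, |Δ| is biased upward at small drift rates because the
absolute value of a noisy difference has a folded-normal mean.

Δ summaries are reported per beam as both the mean and the max over cycle
pairs (the aggregation level behind published per-patient ranges is not
standardised, so neither is silently preferred; the pipeline's headline is
the per-beam mean).

## Gating simulation

Phase gating anchors phase 0 at each detected inspiration peak and
interpolates linearly in time, so the expiration trough of a symmetric
waveform lands at phase 0.5, centred in the 35–65% expiration window.
Amplitude gating normalises the signal to the min/max of the first three
complete cycles; the bounds are then frozen for the rest of the beam,
exactly as a device that calibrates once. Amplitude fractions are **not**
clipped to [0, 1]: a window whose endpoint touches 0 (or 1) is open-ended
beyond the calibration range on that side, because a real device with only
a "low" threshold keeps gating when the target drifts below it. This
choice visibly changes drifted-trace results (the expiration window
follows a sinking trough, keeping a high duty cycle but accumulating drift
spread); a `strict_bounds` mode closes the windows at the calibration
range.

Cycle bookkeeping for both methods runs inspiration peak to inspiration
peak. Residual motion per cycle and direction is the range (max − min) of
beam-on positions; a standard-deviation variant is available. Cycles with
fewer than two beam-on samples contribute 0 mm and stay counted (a
window's displacement over ≤1 sample is zero); an exclusion mode exists.
The 3-D residual is the Euclidean norm of the three per-direction means —
the combination rule behind published signed "3-D residual" differences is
not defined anywhere, so differences are reported as (phase − amplitude)
of the norms.

A genuinely constant signal cannot anchor cycles; rather than failing, the
pipeline treats it as one always-gatable cycle (a motionless target is in
any window), which makes the no-motion limit exact end to end. Non-constant
traces with fewer than two detectable inspiration peaks raise an error
naming the trace.

## Dosimetry

The reference plan replaces a treatment-planning-system phantom plan with
a radially symmetric analytic field

    dose(r) = D_max · ½ (1 + erf((r_edge − r) / (√2 σ)))

with `r_edge` placed so the PTV surface (CTV 23 mm sphere + 5 mm margin)
receives exactly `coverage · D_max` = 48 Gy at 80% coverage
(`D_max = 60 Gy`). The comparison between gating methods depends on the
plateau-plus-penumbra structure and the coverage convention, not on beam
arrangement. Penumbra σ defaults to 5 mm (typical 6 MV beam penumbra),
configurable; on the default grid the unblurred plan's HI is ≈ 0.032.

Beam-on displacement histograms (bin width 1 mm, bin centres aligned to
zero displacement) are taken relative to the *planned position*, defined
as the mean beam-on position during the calibration cycles — the reference
point of the probability axis is otherwise undefined. The dose grid
(default 1 mm isotropic, 81³, axes LR/CC/AP) is blurred by three
sequential 1-D convolutions (a separable product-form 3-D kernel,
following the per-direction construction of the dose-probability method).
The output grid grows by each kernel's half-width so no probability mass
is truncated: the integral is conserved to better than 1e-6 (machine
precision in practice), delta and pure-shift kernels take an exact
integer-shift path, and a grid whose boundary already carries more than
0.1% of D_max refuses to convolve rather than silently losing dose.
Multi-beam analyses pool beams per patient by equal-weight averaging of
the per-direction PDFs (beam weighting is not otherwise defined).

DVH metrics D2/D98/D50 are read off the empirical in-CTV dose distribution
by linear interpolation of order statistics, so a uniform dose returns
exact values; the cumulative curve is also exported at 0.1 Gy resolution.
`P_CTV` integrates the gated-position PDF between the window's intended
amplitude extent fixed at setup: the calibration-mapped levels for
amplitude gating (open-ended sides extend to the PDF support) and the
calibration-cycle beam-on range for phase gating, pro-rating partial bins
linearly.

## Numerical choices and degenerate inputs

* Sampling-quantization tolerance for waveform-level comparisons is the
  one-sample position quantum (max slope × Δt).
* HI rises monotonically with drift rate while the blur width is
  comparable to the dose plateau; once drift travel far exceeds the
  plateau (e.g. 0.7 mm/s over ≥90 s), D50 collapses and HI saturates
  around ~1 non-monotonically. Monotonicity checks therefore use a 45 s
  beam segment.
* Constant signals yield empty expiration series with a warning flag;
  fewer than two expiration points yield an empty drift profile with
  absent summaries; an all-off gating mask yields zero residual motion
  with a warning flag, and an empty window raises before dosimetry.
* Cohort analyses at full scale (148 beams, 81³ grid, patient-level
  pooling: 60 convolutions) complete in well under a minute on one CPU;
  unit and oracle tests use 31³ grids at 2.5 mm spacing.

## Known limitations

* The synthetic cohort reproduces the *qualitative* published findings —
  lobe-dependent drift magnitudes, amplitude gating reducing residual
  motion in transition/inspiration, phase-gating HI exceeding
  amplitude-gating HI in every phase, HI growing with drift. Published
  *absolute* HI values (~1.0) arose from undeposited patient traces and a
  TPS dose and are not reproducible here; only orderings transfer.
* The analytic dose model has no heterogeneity correction, beam geometry
  or interplay effect (consistent with static-field gated 3D-CRT, where
  interplay does not occur).
* Marker-to-target correlation is assumed perfect; gating latency, couch
  corrections and audio-visual coaching are out of scope.
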