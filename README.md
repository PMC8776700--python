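# respigate

Quantitative analysis of intra-beam respiratory motion for respiratory-gated
lung stereotactic body radiotherapy (SBRT).

During a gated lung-SBRT beam the end-expiration position of the target can
drift from cycle to cycle (baseline drift). A gating device fixes its window
during the first few breathing cycles and never re-calibrates, so drift
silently changes *where* the target actually is while the beam is on. This
package quantifies that effect end to end:

1. **Baseline drift.** Per direction (AP, CC, LR), the end-expiration point
   `(t_EPn, A_EPn)` of every cycle is detected and the per-cycle drift rate

   `Δ [mm/s] = |A_EP(n+1) − A_EPn| / (t_EP(n+1) − t_EPn)`

   is summarised per beam.
2. **Gating simulation.** Two clinical schemes are emulated: *phase gating*
   (cycle time normalised to [0,1); expiration window 35–65%, transition
   20–35% ∪ 65–80%, inspiration 0–15% ∪ 85–100%) and *amplitude gating*
   (signal normalised to the min/max of the first three cycles, bounds then
   frozen; expiration 0–30%, transition 35–65%, inspiration 70–100%).
   Residual motion is the per-cycle displacement range of the target while
   the beam is on.
3. **Dosimetry.** The beam-on target positions form a probability density
   `Q(z)` per direction; the probability of the target staying within the
   intended window is `P_CTV = ∫ Q(z) dz` between the window's amplitude
   bounds. A static reference dose (spherical 23 mm CTV + 5 mm PTV margin,
   48 Gy / 4 fractions prescribed to the 80% isodose, error-function
   penumbra) is blurred by `Q` with separable per-direction convolutions
   (the van Herk dose-probability method), and the CTV DVH yields the
   ICRU-83 homogeneity index `HI = (D2 − D98) / D50`.

Because clinical fiducial-marker logs are not freely available, a seeded
synthetic waveform generator provides the inputs: quasi-periodic raised
cosine breathing with per-cycle amplitude/period variability, additive
noise, and a piecewise-linear drifting baseline, including a 148-beam /
10-patient cohort template whose amplitudes (≈10 ± 2 mm), cycles
(≈3.0 ± 0.6 s), beam durations (≈120–185 s) and lobe-dependent drift rates
(up to ≈0.74 mm/s for lower-lobe targets) match the published
characteristics of gated lung-SBRT patients. Every stage is validated
against brute-force oracles (exhaustive extrema scan, dense-grid waveform
evaluation, direct 3-D convolution, voxel-exhaustive DVH).

Intended users: medical-physics researchers studying motion management, and
anyone who needs a tested, scriptable model of gating-window behaviour
under baseline drift.

## Worked example

```python
from respigate import (WaveformSpec, generate_trace, detect_expiration_points,
                       compute_baseline_drift, compare_gating_methods,
                       build_reference_dose, gated_dose_analysis)

spec = WaveformSpec(duration_s=120.0, base_amplitude_mm=(4.0, 10.0, 2.5),
                    base_period_s=3.0,
                    drift_rate_mm_per_s=(-0.05, -0.1, -0.04),
                    amplitude_cv=0.1, period_cv=0.1, noise_sd_mm=0.2, seed=42)
trace = generate_trace(spec)

series = detect_expiration_points(trace, "cc", refine_half_width_s="auto")
profile = compute_baseline_drift(series)
print(f"CC baseline drift: mean {profile.summary['mean']:.3f} mm/s, "
      f"max {profile.summary['max']:.3f} mm/s over {len(series)-1} cycle pairs")

table = compare_gating_methods(trace)
print(table[["method", "phase", "cc_mm", "residual_3d_mm", "duty_cycle"]]
      .round(2).to_string(index=False))

reference = build_reference_dose()
for method in ("phase", "amplitude"):
    res = gated_dose_analysis(trace, method, "expiration", reference=reference)
    print(f"{method:9s} expiration: HI = {res.hi:.3f}, P_CTV = {res.p_ctv:.2f}")
```

prints

```
CC baseline drift: mean 0.100 mm/s, max 0.156 mm/s over 38 cycle pairs
   method       phase  cc_mm  residual_3d_mm  duty_cycle
    phase  expiration   2.66            3.15        0.29
    phase  transition   5.23            5.91        0.29
    phase inspiration   3.16            3.67        0.29
amplitude  expiration   7.71            8.78        0.70
amplitude  transition   1.61            2.05        0.15
amplitude inspiration   0.62            0.76        0.06
phase     expiration: HI = 0.275, P_CTV = 0.16
amplitude expiration: HI = 0.184, P_CTV = 0.98
```

Reading the numbers: the detector recovers the generated 0.1 mm/s CC drift
exactly. Phase gating keeps a fixed ~29% duty cycle and its in-window
positions spread as the baseline sinks (HI rises to 0.275, and only 16% of
the delivered-dose probability stays inside the amplitude band the window
was planned at). The amplitude method's expiration window is open below its
calibration floor — like a device with only a "low" threshold — so it
follows the drifting trough (duty 0.70, residual range includes the drift
travel), but the positions stay inside the intended band (P_CTV = 0.98) and
the dose stays more homogeneous (HI = 0.184, reference-plan HI = 0.032).
In the transition and inspiration windows the amplitude method cuts
residual motion from ~5.9/3.7 mm to ~2.1/0.8 mm.

## Command line

```sh
respigate all --config config.yaml --seed 1 --out run/
```

Subcommands `simulate`, `drift`, `gate`, `dose` and `all` consume/produce
the documented CSV/JSON formats (`drift_summary.csv`,
`residual_motion.csv`, `hi_table.csv`, `summary.json`), so stages can be
rerun independently; identical config + seed gives byte-identical outputs.

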