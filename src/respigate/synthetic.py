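"""Synthetic respiratory waveform generator.

Generates quasi-periodic breathing traces with per-cycle amplitude/period
variability, a piecewise-linear drifting baseline and additive Gaussian
noise, so that every downstream stage of the analysis (drift quantification,
gating simulation, dosimetry) is testable without patient data.

Model
-----
Per direction ``d`` the position is

    position_d(t) = baseline_d(t) + sign_d * A_{k,d} * s(phi(t)) + eps(t)

where ``s(phi) = ((1 - cos(2 pi phi)) / 2) ** shape_power`` is a raised
cosine (``shape_power = 1``) or a sharpened-trough variant (``> 1``), the
cycle phase ``phi`` advances by one per breathing cycle, cycle ``k`` draws
its peak-to-peak amplitude ``A_{k,d} ~ Normal(base_d, cv * base_d)``
(clipped at 0) and its period ``T_k ~ Normal(base, cv * base)`` (clipped at
``0.2 * base``), the baseline integrates the configured drift rate, and
``eps ~ Normal(0, noise_sd)``.  Inspiration is the positive extreme;
end-expiration (the trough) sits on the drifting baseline.

The default population parameters emulate a lung-SBRT fiducial-marker
cohort: dominant (CC) amplitude 10.1 +/- 2.2 mm, cycle 3.0 +/- 0.6 s,
beam-on durations of roughly 120-185 s, and per-cycle baseline-drift rates
up to ~0.74 mm/s concentrated in lower-lobe targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace import DIRECTIONS, RespiratoryTrace

# Per-direction drift: a constant rate (mm/s) or piecewise-linear segments
# given as a sequence of (t_start_s, rate_mm_per_s) pairs with t_start[0] == 0.
DriftLike = float | Sequence[tuple[float, float]]


@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of one synthetic trace.

    Amplitudes are peak-to-peak per direction (AP, CC, LR) in mm;
    ``drift_rate_mm_per_s`` is per direction, either a constant rate or a
    list of ``(t_start_s, rate)`` segments.  ``amplitude_cv`` / ``period_cv``
    are coefficients of variation of the per-cycle draws.  A fixed ``seed``
    yields a bit-identical trace.
    """

    duration_s: float
    sample_rate_hz: float = 30.0
    base_amplitude_mm: tuple[float, float, float] = (4.0, 10.1, 2.5)
    base_period_s: float = 3.0
    drift_rate_mm_per_s: tuple[DriftLike, DriftLike, DriftLike] = (0.0, 0.0, 0.0)
    amplitude_cv: float = 0.0
    period_cv: float = 0.0
    noise_sd_mm: float = 0.0
    shape_power: float = 1.0
    sign: tuple[int, int, int] = (1, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        validate_spec(self)


def _check_scalar(name: str, value: float, minimum: float | None = None,
                  strict: bool = False) -> None:
    v = float(value)
    if not np.isfinite(v):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if minimum is not None and (v < minimum or (strict and v <= minimum)):
        op = ">" if strict else ">="
        raise ValueError(f"{name} must be {op} {minimum}, got {value!r}")


def validate_spec(spec: WaveformSpec) -> None:
    """Raise ``ValueError`` naming the offending field of a bad spec."""
    _check_scalar("duration_s", spec.duration_s, 0.0, strict=True)
    _check_scalar("sample_rate_hz", spec.sample_rate_hz, 0.0, strict=True)
    _check_scalar("base_period_s", spec.base_period_s, 0.0, strict=True)
    _check_scalar("amplitude_cv", spec.amplitude_cv, 0.0)
    _check_scalar("period_cv", spec.period_cv, 0.0)
    _check_scalar("noise_sd_mm", spec.noise_sd_mm, 0.0)
    _check_scalar("shape_power", spec.shape_power, 0.0, strict=True)
    if len(spec.base_amplitude_mm) != 3:
        raise ValueError("base_amplitude_mm must have 3 components (AP, CC, LR)")
    for a in spec.base_amplitude_mm:
        _check_scalar("base_amplitude_mm", a, 0.0)
    if len(spec.drift_rate_mm_per_s) != 3:
        raise ValueError("drift_rate_mm_per_s must have 3 components (AP, CC, LR)")
    for d in spec.drift_rate_mm_per_s:
        if np.isscalar(d):
            _check_scalar("drift_rate_mm_per_s", float(d))
        else:
            segs = list(d)
            if not segs or float(segs[0][0]) != 0.0:
                raise ValueError("drift_rate_mm_per_s segments must start at t=0")
            starts = [float(s[0]) for s in segs]
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise ValueError("drift_rate_mm_per_s segment starts must increase")
            for _, r in segs:
                _check_scalar("drift_rate_mm_per_s", float(r))
    if len(spec.sign) != 3 or any(s not in (-1, 1) for s in spec.sign):
        raise ValueError("sign must be a 3-tuple of +/-1")
    if int(spec.seed) != spec.seed:
        raise ValueError("seed must be an integer")


# -- closed-form pieces ---------------------------------------------------

def baseline_mm(drift: DriftLike, t: np.ndarray) -> np.ndarray:
    """Integrated baseline offset at times ``t`` for one direction's drift."""
    t = np.asarray(t, dtype=float)
    if np.isscalar(drift):
        return float(drift) * t
    segs = list(drift)
    starts = np.array([float(s[0]) for s in segs])
    rates = np.array([float(s[1]) for s in segs])
    # offset accumulated at each segment start
    seg_len = np.diff(starts)
    offsets = np.concatenate([[0.0], np.cumsum(rates[:-1] * seg_len)])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(segs) - 1)
    return offsets[idx] + rates[idx] * (t - starts[idx])


def cycle_structure(spec: WaveformSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reproduce the per-cycle draws of ``generate_trace``.

    Returns ``(start_times, periods, amplitudes)`` with ``amplitudes`` of
    shape ``(n_cycles, 3)``.  Cycle ``k`` spans ``[start[k], start[k] + T[k])``
    and its trough (expiration) lies at ``start[k]`` on the baseline.
    """
    rng = np.random.default_rng(spec.seed)
    base_t = spec.base_period_s
    periods: list[float] = []
    total = 0.0
    while total < spec.duration_s + base_t:
        t_k = float(rng.normal(base_t, spec.period_cv * base_t))
        t_k = max(t_k, 0.2 * base_t)
        periods.append(t_k)
        total += t_k
    periods_a = np.array(periods)
    starts = np.concatenate([[0.0], np.cumsum(periods_a)[:-1]])
    base_amp = np.asarray(spec.base_amplitude_mm, dtype=float)
    amps = rng.normal(base_amp, spec.amplitude_cv * base_amp, size=(len(periods), 3))
    amps = np.maximum(amps, 0.0)
    return starts, periods_a, amps


def evaluate_waveform(spec: WaveformSpec, t: np.ndarray) -> np.ndarray:
    """Noiseless closed-form waveform of ``spec`` at arbitrary times ``t``.

    Used by the generator itself at the sample grid and by dense-grid test
    oracles between samples.  Shape ``(len(t), 3)``.
    """
    t = np.asarray(t, dtype=float)
    starts, periods, amps = cycle_structure(spec)
    k = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    phase_frac = (t - starts[k]) / periods[k]
    shape = ((1.0 - np.cos(2.0 * np.pi * phase_frac)) / 2.0) ** spec.shape_power
    pos = np.empty((t.size, 3))
    for d in range(3):
        pos[:, d] = (
            baseline_mm(spec.drift_rate_mm_per_s[d], t)
            + spec.sign[d] * amps[k, d] * shape
        )
    return pos


def trough_times(spec: WaveformSpec) -> np.ndarray:
    """Analytic end-expiration times (cycle starts) inside the trace."""
    starts, _, _ = cycle_structure(spec)
    return starts[starts <= spec.duration_s]


def generate_trace(spec: WaveformSpec, meta: dict | None = None) -> RespiratoryTrace:
    """Generate one trace from ``spec`` (deterministic for a fixed seed)."""
    validate_spec(spec)
    n = int(round(spec.duration_s * spec.sample_rate_hz)) + 1
    t = np.arange(n) / spec.sample_rate_hz
    pos = evaluate_waveform(spec, t)
    if spec.noise_sd_mm > 0:
        # separate, seed-derived stream so the cycle draws are unaffected
        noise_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
        pos = pos + noise_rng.normal(0.0, spec.noise_sd_mm, size=pos.shape)
    full_meta = {"source": "synthetic", "seed": int(spec.seed)}
    if meta:
        full_meta.update(meta)
    return RespiratoryTrace(time_s=t, position_mm=pos, meta=full_meta)


# -- cohorts --------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Population distributions for generic cohorts.

    Per trace, the dominant (CC) peak-to-peak amplitude is drawn
    ``Normal(amplitude_mean_mm, amplitude_sd_mm)``, the mean cycle
    ``Normal(period_mean_s, period_sd_s)``, the beam duration
    ``Normal(duration_mean_s, duration_sd_s)`` clipped to
    ``[duration_min_s, duration_max_s]``, and the CC drift magnitude
    ``Uniform(*drift_cc_range_mm_per_s)`` with a random sign; AP and LR
    amplitudes and drifts scale off CC (lung targets move predominantly
    cranio-caudally).
    """

    amplitude_mean_mm: float = 10.1
    amplitude_sd_mm: float = 2.2
    period_mean_s: float = 3.0
    period_sd_s: float = 0.6
    duration_mean_s: float = 156.0
    duration_sd_s: float = 20.0
    duration_min_s: float = 120.0
    duration_max_s: float = 185.0
    drift_cc_range_mm_per_s: tuple[float, float] = (0.06, 0.74)
    ap_amplitude_fraction: float = 0.4
    lr_amplitude_fraction: float = 0.25
    ap_drift_fraction: float = 0.54
    lr_drift_fraction: float = 0.50
    amplitude_cv: float = 0.15
    period_cv: float = 0.15
    noise_sd_mm: float = 0.15
    sample_rate_hz: float = 30.0
    drift_style: str = "constant"  # "constant" | "wandering"


def _wandering_drift(rng: np.random.Generator, duration_s: float,
                     magnitude: float, excursion_cap_mm: float = 8.0
                     ) -> tuple[tuple[float, float], ...]:
    """Piecewise-linear drift: |rate| = magnitude, sign reflects the baseline
    inside ``+/- excursion_cap_mm`` so the per-cycle slope matches the drawn
    magnitude without unphysical net travel."""
    segs: list[tuple[float, float]] = []
    t, b = 0.0, 0.0
    sign = -1.0 if rng.random() < 0.5 else 1.0
    while t < duration_s:
        seg = float(rng.uniform(10.0, 20.0))
        if rng.random() < 0.3:
            sign = -sign
        if abs(b + sign * magnitude * seg) > excursion_cap_mm:
            sign = -sign
        segs.append((t, sign * magnitude))
        b += sign * magnitude * seg
        t += seg
    return tuple(segs)


def _scaled_drift(drift_cc: DriftLike, fraction: float) -> DriftLike:
    if np.isscalar(drift_cc):
        return float(drift_cc) * fraction
    return tuple((t0, r * fraction) for t0, r in drift_cc)


def _draw_spec(rng: np.random.Generator, pop: PopulationParams) -> WaveformSpec:
    amp_cc = max(2.0, float(rng.normal(pop.amplitude_mean_mm, pop.amplitude_sd_mm)))
    period = max(0.8, float(rng.normal(pop.period_mean_s, pop.period_sd_s)))
    duration = float(
        np.clip(rng.normal(pop.duration_mean_s, pop.duration_sd_s),
                pop.duration_min_s, pop.duration_max_s)
    )
    mag = float(rng.uniform(*pop.drift_cc_range_mm_per_s))
    sign = -1.0 if rng.random() < 0.5 else 1.0
    if pop.drift_style == "wandering":
        drift_cc: DriftLike = _wandering_drift(rng, duration, mag)
    else:
        drift_cc = sign * mag
    seed = int(rng.integers(2**31))
    return WaveformSpec(
        duration_s=duration,
        sample_rate_hz=pop.sample_rate_hz,
        base_amplitude_mm=(amp_cc * pop.ap_amplitude_fraction, amp_cc,
                           amp_cc * pop.lr_amplitude_fraction),
        base_period_s=period,
        drift_rate_mm_per_s=(
            _scaled_drift(drift_cc, pop.ap_drift_fraction),
            drift_cc,
            _scaled_drift(drift_cc, pop.lr_drift_fraction),
        ),
        amplitude_cv=pop.amplitude_cv,
        period_cv=pop.period_cv,
        noise_sd_mm=pop.noise_sd_mm,
        seed=seed,
    )


def generate_cohort(n_traces: int, population: PopulationParams | None = None,
                    seed: int = 0) -> list[RespiratoryTrace]:
    """Generate ``n_traces`` independent traces from a population (seeded)."""
    if n_traces < 1:
        raise ValueError(f"n_traces must be >= 1, got {n_traces}")
    pop = population or PopulationParams()
    rng = np.random.default_rng(seed)
    traces = []
    for i in range(n_traces):
        spec = _draw_spec(rng, pop)
        traces.append(generate_trace(spec, meta={"trace_id": f"t{i:03d}",
                                                 "cohort_seed": int(seed),
                                                 "spec": spec}))
    return traces


# Lung-SBRT cohort template: per patient (n_beams == usable data sets,
# dominant-amplitude mean/sd mm, cycle mean/sd s, beam time mean/sd s, lobe).
CLINICAL_PATIENTS: tuple[dict, ...] = (
    {"patient": "p01", "n_beams": 10, "amp": (14.0, 2.5), "cycle": (2.7, 0.4),
     "time": (166.0, 16.0), "lobe": "middle"},
    {"patient": "p02", "n_beams": 15, "amp": (8.7, 1.6), "cycle": (2.3, 0.2),
     "time": (179.0, 22.0), "lobe": "middle"},
    {"patient": "p03", "n_beams": 13, "amp": (8.3, 0.9), "cycle": (2.1, 0.2),
     "time": (166.0, 16.0), "lobe": "middle"},
    {"patient": "p04", "n_beams": 14, "amp": (6.4, 1.2), "cycle": (4.7, 0.7),
     "time": (166.0, 20.0), "lobe": "upper"},
    {"patient": "p05", "n_beams": 20, "amp": (9.3, 1.4), "cycle": (2.2, 0.3),
     "time": (185.0, 20.0), "lobe": "upper"},
    {"patient": "p06", "n_beams": 13, "amp": (10.6, 2.5), "cycle": (2.8, 0.5),
     "time": (122.0, 14.0), "lobe": "lower"},
    {"patient": "p07", "n_beams": 14, "amp": (13.4, 1.8), "cycle": (3.0, 0.4),
     "time": (130.0, 25.0), "lobe": "lower"},
    {"patient": "p08", "n_beams": 16, "amp": (11.0, 3.4), "cycle": (3.4, 0.9),
     "time": (145.0, 10.0), "lobe": "lower"},
    {"patient": "p09", "n_beams": 18, "amp": (10.5, 4.3), "cycle": (3.3, 1.0),
     "time": (160.0, 17.0), "lobe": "lower"},
    {"patient": "p10", "n_beams": 15, "amp": (8.9, 2.2), "cycle": (3.4, 1.1),
     "time": (138.0, 12.0), "lobe": "lower"},
)

#: Per-cycle CC drift-rate magnitude range (mm/s) by lung-lobe class.
LOBE_DRIFT_RANGES = {
    "upper": (0.03, 0.13),
    "middle": (0.06, 0.30),
    "lower": (0.30, 0.74),
}


def generate_clinical_cohort(seed: int = 0,
                             patients: Sequence[dict] | None = None,
                             beams_per_patient: int | None = None,
                             sample_rate_hz: float = 30.0,
                             noise_sd_mm: float = 0.15,
                             ) -> list[RespiratoryTrace]:
    """Generate the default study cohort: 148 beams across 10 patients.

    Each patient keeps a fixed lobe class that sets the range of per-beam
    baseline-drift magnitudes (upper-lobe targets drift least, lower-lobe
    most); each beam draws its own amplitude, mean cycle, duration and
    wandering piecewise-linear baseline.  ``beams_per_patient`` caps the
    number of beams per patient (for quick runs); by default the full
    template counts are used.
    """
    rng = np.random.default_rng(seed)
    traces: list[RespiratoryTrace] = []
    for pat in (patients or CLINICAL_PATIENTS):
        n_beams = pat["n_beams"] if beams_per_patient is None else min(
            pat["n_beams"], beams_per_patient)
        lo, hi = LOBE_DRIFT_RANGES[pat["lobe"]]
        pop = PopulationParams(
            amplitude_mean_mm=pat["amp"][0], amplitude_sd_mm=pat["amp"][1],
            period_mean_s=pat["cycle"][0], period_sd_s=pat["cycle"][1],
            duration_mean_s=pat["time"][0], duration_sd_s=pat["time"][1],
            drift_cc_range_mm_per_s=(lo, hi),
            noise_sd_mm=noise_sd_mm, sample_rate_hz=sample_rate_hz,
            drift_style="wandering",
        )
        for b in range(n_beams):
            spec = _draw_spec(rng, pop)
            traces.append(generate_trace(spec, meta={
                "trace_id": f"{pat['patient']}_b{b:02d}",
                "patient": pat["patient"],
                "beam": f"b{b:02d}",
                "lobe": pat["lobe"],
                "spec": spec,
            }))
    return traces


def cohort_manifest(traces: Sequence[RespiratoryTrace],
                    paths: Sequence[str] | None = None) -> list[dict]:
    """JSON-serializable manifest of per-trace metadata (and file paths)."""
    entries = []
    for i, tr in enumerate(traces):
        entry = dict(tr.meta)
        if isinstance(entry.get("spec"), WaveformSpec):
            entry["spec"] = dataclasses.asdict(entry["spec"])
        entry.update(n_samples=tr.n_samples, duration_s=tr.duration_s,
                     sample_rate_hz=tr.sample_rate_hz)
        if paths is not None:
            entry["path"] = str(paths[i])
        entries.append(entry)
    return entries
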