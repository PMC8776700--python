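"""Phase- and amplitude-gating simulation and residual-motion analysis.

Two gating schemes are simulated the way a clinical gating device applies
them:

* **Phase gating** — each breathing cycle is normalised to [0, 1) in *time*
  between consecutive inspiration peaks (phase 0 = inspiration, so the
  expiration trough of a symmetric waveform lands at phase 0.5).  The beam
  is on whenever the phase fraction falls inside the window intervals
  (defaults: expiration 35-65%, transition 20-35% + 65-80%, inspiration
  0-15% + 85-100%).
* **Amplitude gating** — the signal is normalised to the minimum/maximum
  amplitude of the first few (default three) cycles; those bounds are then
  FIXED for the rest of the beam, exactly as a gating device that
  calibrates once at the start and never re-calibrates.  The beam is on
  whenever the normalised amplitude falls inside the window intervals
  (defaults: expiration 0-30%, transition 35-65%, inspiration 70-100%).
  Amplitude fractions are *not* clipped: after baseline drift the signal
  may leave the calibration range, and a window whose endpoint touches 0
  (or 1) is treated as open-ended on that side -- a device with only a
  "low" threshold keeps gating when the target drifts below it.  A
  ``strict_bounds`` mode closes the windows at the calibration range.

Residual motion is the displacement of the target per cycle while the beam
is on: per cycle and direction the range (max - min) of the beam-on
positions, averaged over cycles, with the 3-D residual the Euclidean norm
of the three per-direction means.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .drift import (DEFAULT_PROMINENCE_FRACTION, detect_inspiration_peaks)
from .trace import DIRECTIONS, RespiratoryTrace

METHODS = ("phase", "amplitude")
PHASES = ("expiration", "transition", "inspiration")

#: Default gating windows as fractions (phase of cycle, or normalised amplitude).
PHASE_WINDOWS = {
    "expiration": ((0.35, 0.65),),
    "transition": ((0.20, 0.35), (0.65, 0.80)),
    "inspiration": ((0.0, 0.15), (0.85, 1.0)),
}
AMPLITUDE_WINDOWS = {
    "expiration": ((0.0, 0.30),),
    "transition": ((0.35, 0.65),),
    "inspiration": ((0.70, 1.0),),
}


class GatingError(ValueError):
    """Gating cannot be performed on this trace."""


@dataclass(frozen=True)
class GatingWindowSpec:
    """A gating window: method, named phase, and fraction intervals."""

    method: str
    phase_name: str
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.phase_name not in PHASES:
            raise ValueError(f"phase_name must be one of {PHASES}")
        ivs = sorted(self.intervals)
        for lo, hi in ivs:
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"bad interval [{lo}, {hi}]")
        for (_, hi1), (lo2, _) in zip(ivs, ivs[1:]):
            if lo2 < hi1:
                raise ValueError("intervals overlap")

    @property
    def total_width(self) -> float:
        return float(sum(hi - lo for lo, hi in self.intervals))

    @classmethod
    def default(cls, method: str, phase_name: str) -> "GatingWindowSpec":
        table = PHASE_WINDOWS if method == "phase" else AMPLITUDE_WINDOWS
        return cls(method=method, phase_name=phase_name,
                   intervals=table[phase_name])


@dataclass
class PhaseAssignment:
    """Per-sample cycle bookkeeping for one trace.

    ``phase_fraction`` is NaN and ``cycle_index`` is -1 for samples before
    the first / after the last inspiration-peak anchor (out-of-cycle samples
    are excluded from gating).  ``amplitude_fraction`` is filled by
    :func:`normalize_amplitude` and may exceed [0, 1] once the signal leaves
    the calibration range.  ``static`` marks the degenerate constant-signal
    fallback (whole trace treated as one always-gatable cycle).
    """

    gating_direction: str
    phase_fraction: np.ndarray
    cycle_index: np.ndarray
    anchor_indices: np.ndarray
    amplitude_fraction: np.ndarray | None = None
    static: bool = False

    @property
    def n_cycles(self) -> int:
        if self.static:
            return 1
        return max(0, int(self.anchor_indices.size) - 1)

    @property
    def in_cycle(self) -> np.ndarray:
        return self.cycle_index >= 0


@dataclass
class BeamOnMask:
    """Boolean beam-on flag per sample plus overall duty cycle."""

    on: np.ndarray
    duty_cycle: float

    def __post_init__(self) -> None:
        self.on = np.asarray(self.on, dtype=bool)


@dataclass
class ResidualMotionResult:
    """Per-cycle in-window target displacement.

    ``per_cycle_range_mm`` has shape ``(n_cycles, 3)`` (AP, CC, LR);
    ``mean_mm`` is the per-direction mean over cycles and
    ``residual_3d_mm`` the Euclidean norm of those means.  ``all_off``
    warns that the mask never fired.
    """

    per_cycle_range_mm: np.ndarray
    mean_mm: np.ndarray
    residual_3d_mm: float
    all_off: bool = False


def assign_phase(trace: RespiratoryTrace, gating_direction: str = "cc",
                 min_period_s: float | None = None,
                 prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
                 sign: int = 1,
                 static_fallback: bool = False) -> PhaseAssignment:
    """Anchor phase 0 at each inspiration peak and interpolate linearly.

    Each cycle ``[peak_k, peak_{k+1})`` maps to phase [0, 1).  Fewer than
    two detectable inspiration peaks raise :class:`GatingError` naming the
    trace -- except for a genuinely constant signal when
    ``static_fallback=True``, which yields a degenerate all-in-cycle
    assignment (a motionless target is gatable in any window).
    """
    x = trace.direction(gating_direction)
    n = x.size
    if np.ptp(x) == 0 and static_fallback:
        return PhaseAssignment(
            gating_direction=gating_direction,
            phase_fraction=np.zeros(n),
            cycle_index=np.zeros(n, dtype=int),
            anchor_indices=np.array([0, n - 1]),
            static=True,
        )
    peaks = detect_inspiration_peaks(trace, gating_direction,
                                     min_period_s=min_period_s,
                                     prominence_fraction=prominence_fraction,
                                     sign=sign)
    if peaks.size < 2:
        raise GatingError(
            f"trace {trace.trace_id!r}: need >= 2 inspiration peaks in "
            f"direction {gating_direction!r}, found {peaks.size}"
        )
    t = trace.time_s
    cycle = np.searchsorted(t[peaks], t, side="right") - 1
    cycle[cycle >= peaks.size - 1] = -1  # at/after last anchor
    phase = np.full(n, np.nan)
    ok = cycle >= 0
    k = cycle[ok]
    phase[ok] = (t[ok] - t[peaks[k]]) / (t[peaks[k + 1]] - t[peaks[k]])
    return PhaseAssignment(gating_direction=gating_direction,
                           phase_fraction=phase,
                           cycle_index=cycle,
                           anchor_indices=peaks)


def calibrate_amplitude(trace: RespiratoryTrace, assignment: PhaseAssignment,
                        n_calibration_cycles: int = 3) -> tuple[float, float]:
    """Min/max of the gating signal over the first ``n_calibration_cycles``
    complete cycles.  These bounds stay fixed for the rest of the beam."""
    x = trace.direction(assignment.gating_direction)
    if assignment.static:
        return float(x[0]), float(x[0])
    if assignment.n_cycles < n_calibration_cycles:
        raise GatingError(
            f"calibration needs {n_calibration_cycles} complete cycles, "
            f"trace has {assignment.n_cycles}"
        )
    sel = (assignment.cycle_index >= 0) & (assignment.cycle_index < n_calibration_cycles)
    return float(x[sel].min()), float(x[sel].max())


def normalize_amplitude(trace: RespiratoryTrace, assignment: PhaseAssignment,
                        calibration: tuple[float, float]) -> PhaseAssignment:
    """Attach the unclipped normalised amplitude ``(x - a_min)/(a_max - a_min)``."""
    a_min, a_max = calibration
    x = trace.direction(assignment.gating_direction)
    if a_max > a_min:
        frac = (x - a_min) / (a_max - a_min)
    else:
        frac = np.zeros_like(x)
    return dataclasses.replace(assignment, amplitude_fraction=frac)


@dataclass
class GatingContext:
    """Everything needed to gate one trace: assignment + calibration."""

    trace: RespiratoryTrace
    assignment: PhaseAssignment
    calibration: tuple[float, float]


def prepare_gating(trace: RespiratoryTrace, gating_direction: str = "cc",
                   n_calibration_cycles: int = 3,
                   min_period_s: float | None = None,
                   prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
                   sign: int = 1,
                   static_fallback: bool = True) -> GatingContext:
    """Assign phase, calibrate and normalise amplitude for one trace."""
    assignment = assign_phase(trace, gating_direction,
                              min_period_s=min_period_s,
                              prominence_fraction=prominence_fraction,
                              sign=sign, static_fallback=static_fallback)
    calibration = calibrate_amplitude(trace, assignment, n_calibration_cycles)
    assignment = normalize_amplitude(trace, assignment, calibration)
    return GatingContext(trace=trace, assignment=assignment,
                         calibration=calibration)


def compute_gating_mask(assignment: PhaseAssignment, window: GatingWindowSpec,
                        strict_bounds: bool = False) -> BeamOnMask:
    """Beam-on mask for one window.

    Phase method: on iff the phase fraction lies in an interval (closed).
    Amplitude method: on iff the normalised amplitude lies in an interval,
    with intervals touching 0 (1) open-ended below (above) the calibration
    range unless ``strict_bounds``.  Out-of-cycle samples are always off.
    """
    if assignment.static:
        on = assignment.in_cycle.copy()
        return BeamOnMask(on=on, duty_cycle=float(on.mean()))
    if window.method == "phase":
        values = assignment.phase_fraction
    else:
        if assignment.amplitude_fraction is None:
            raise GatingError("amplitude gating requires a calibrated assignment")
        values = assignment.amplitude_fraction
    on = np.zeros(values.size, dtype=bool)
    with np.errstate(invalid="ignore"):
        for lo, hi in window.intervals:
            lo_eff, hi_eff = lo, hi
            if window.method == "amplitude" and not strict_bounds:
                if lo == 0.0:
                    lo_eff = -np.inf
                if hi == 1.0:
                    hi_eff = np.inf
            on |= (values >= lo_eff) & (values <= hi_eff)
    on &= assignment.in_cycle
    return BeamOnMask(on=on, duty_cycle=float(on.mean()))


def compute_residual_motion(trace: RespiratoryTrace, mask: BeamOnMask,
                            cycle_index: np.ndarray,
                            per_cycle_metric: str = "range",
                            empty_cycle_policy: str = "zero",
                            ) -> ResidualMotionResult:
    """Per-cycle in-window displacement, per direction, plus the 3-D norm.

    Cycles with fewer than two beam-on samples contribute 0 mm and are
    counted (``empty_cycle_policy="zero"``; ``"exclude"`` drops them).
    """
    if per_cycle_metric not in ("range", "sd"):
        raise ValueError(f"unknown per_cycle_metric {per_cycle_metric!r}")
    cycles = np.unique(cycle_index[cycle_index >= 0])
    per_cycle = np.zeros((cycles.size, 3))
    counted = np.ones(cycles.size, dtype=bool)
    for row, k in enumerate(cycles):
        sel = mask.on & (cycle_index == k)
        if sel.sum() < 2:
            counted[row] = empty_cycle_policy == "zero"
            continue
        pos = trace.position_mm[sel]
        if per_cycle_metric == "range":
            per_cycle[row] = pos.max(axis=0) - pos.min(axis=0)
        else:
            per_cycle[row] = pos.std(axis=0, ddof=0)
    all_off = not bool(mask.on.any())
    kept = per_cycle[counted] if counted.any() else np.zeros((0, 3))
    mean = kept.mean(axis=0) if kept.size else np.zeros(3)
    return ResidualMotionResult(per_cycle_range_mm=per_cycle,
                                mean_mm=mean,
                                residual_3d_mm=float(np.linalg.norm(mean)),
                                all_off=all_off)


def compare_gating_methods(trace: RespiratoryTrace, gating_direction: str = "cc",
                           n_calibration_cycles: int = 3,
                           strict_bounds: bool = False,
                           per_cycle_metric: str = "range",
                           context: GatingContext | None = None) -> pd.DataFrame:
    """Residual motion for both methods over all three phase windows.

    Returns one row per method x phase with per-direction mean residuals
    (mm), the 3-D residual, and the duty cycle.
    """
    ctx = context or prepare_gating(trace, gating_direction,
                                    n_calibration_cycles=n_calibration_cycles)
    rows = []
    for method in METHODS:
        for phase in PHASES:
            window = GatingWindowSpec.default(method, phase)
            mask = compute_gating_mask(ctx.assignment, window,
                                       strict_bounds=strict_bounds)
            res = compute_residual_motion(trace, mask, ctx.assignment.cycle_index,
                                          per_cycle_metric=per_cycle_metric)
            rows.append({
                "trace_id": trace.trace_id,
                "method": method,
                "phase": phase,
                "ap_mm": res.mean_mm[0],
                "cc_mm": res.mean_mm[1],
                "lr_mm": res.mean_mm[2],
                "residual_3d_mm": res.residual_3d_mm,
                "duty_cycle": mask.duty_cycle,
                "all_off": res.all_off,
            })
    return pd.DataFrame(rows)


def residual_difference(table: pd.DataFrame) -> pd.DataFrame:
    """Signed (phase - amplitude) residual differences per phase.

    Differences of the per-direction means and of the 3-D norms, mirroring a
    per-phase method comparison.
    """
    cols = ["ap_mm", "cc_mm", "lr_mm", "residual_3d_mm"]
    ph = table[table.method == "phase"].set_index("phase")[cols]
    am = table[table.method == "amplitude"].set_index("phase")[cols]
    diff = (ph - am).reset_index()
    diff.insert(0, "comparison", "phase_minus_amplitude")
    return diff
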