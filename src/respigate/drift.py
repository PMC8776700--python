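"""Per-cycle expiration-point detection and baseline-drift quantification.

The baseline-drift rate between consecutive breathing cycles is

    delta_n [mm/s] = |A_EP_{n+1} - A_EP_n| / (t_EP_{n+1} - t_EP_n)

where ``(t_EP_n, A_EP_n)`` is the end-expiration point of cycle ``n`` in a
given anatomical direction.  Expiration points are local minima of the
signal (under the convention that inspiration is the positive extreme),
found with a minimum inter-minimum spacing and a prominence floor so that
noise wiggles and double-dip troughs do not split a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .trace import DIRECTIONS, RespiratoryTrace

DEFAULT_PROMINENCE_FRACTION = 0.3


@dataclass
class ExpirationSeries:
    """Per-cycle expiration points ``(t_EP_n, A_EP_n)`` for one direction."""

    direction: str
    t_ep: np.ndarray
    a_ep: np.ndarray
    min_period_s: float = 0.0
    constant_signal: bool = False  # warning flag: zero-range input

    def __post_init__(self) -> None:
        self.t_ep = np.asarray(self.t_ep, dtype=float)
        self.a_ep = np.asarray(self.a_ep, dtype=float)
        if self.t_ep.shape != self.a_ep.shape:
            raise ValueError("t_ep and a_ep must have equal length")
        if self.t_ep.size and np.any(np.diff(self.t_ep) <= 0):
            raise ValueError("t_ep must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t_ep.size)


@dataclass
class DriftProfile:
    """Per-cycle-pair drift rates and per-beam summary for one direction.

    ``summary`` holds ``{"mean", "max", "p95"}`` in mm/s, or ``None`` when
    fewer than two expiration points were available (``empty`` flag set).
    """

    direction: str
    delta_mm_per_s: np.ndarray
    t_mid_s: np.ndarray
    summary: dict | None = None

    @property
    def empty(self) -> bool:
        return self.delta_mm_per_s.size == 0


def estimate_cycle_period(x: np.ndarray, sample_rate_hz: float) -> float | None:
    """Dominant breathing period from the autocorrelation of the detrended
    signal; ``None`` if no periodicity is detectable."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return None
    t = np.arange(n)
    coeffs = np.polyfit(t, x, 1)
    x0 = x - np.polyval(coeffs, t)
    if np.allclose(x0, 0):
        return None
    ac = np.correlate(x0, x0, mode="full")[n - 1:]
    peaks, _ = find_peaks(ac)
    peaks = peaks[(peaks > 1) & (ac[peaks] > 0.1 * ac[0])]
    if peaks.size == 0:
        return None
    return float(peaks[0] / sample_rate_hz)


def oscillation_range(x: np.ndarray, sample_rate_hz: float,
                      min_period_s: float) -> float:
    """Peak-to-peak range of the breathing oscillation alone.

    The slow baseline (drift, wander) is removed with a one-cycle centred
    moving average before taking the range, so the prominence floor tracks
    the per-cycle oscillation even when the baseline travels further than
    the breathing amplitude.  On a stationary waveform this equals the raw
    peak-to-peak range.
    """
    from scipy.ndimage import uniform_filter1d
    window = max(3, int(round(2.0 * min_period_s * sample_rate_hz)))
    baseline = uniform_filter1d(np.asarray(x, float), size=window,
                                mode="nearest")
    return float(np.ptp(x - baseline))


def _find_extrema(x: np.ndarray, sample_rate_hz: float, kind: str,
                  min_period_s: float | None,
                  prominence_fraction: float) -> tuple[np.ndarray, float]:
    """Indices of local minima (``kind='min'``) or maxima of ``x`` subject to
    the spacing/prominence contract.  Returns ``(indices, min_period_s)``."""
    if not 0 < prominence_fraction <= 1:
        raise ValueError("prominence_fraction must be in (0, 1]")
    if np.ptp(x) == 0:
        return np.array([], dtype=int), min_period_s or 0.0
    if min_period_s is None:
        est = estimate_cycle_period(x, sample_rate_hz)
        min_period_s = 0.5 * est if est is not None else 1.0
    if min_period_s <= 0:
        raise ValueError("min_period_s must be > 0")
    value_range = oscillation_range(x, sample_rate_hz, min_period_s)
    distance = max(1, int(round(min_period_s * sample_rate_hz)))
    signal = -x if kind == "min" else x
    idx, _ = find_peaks(signal, distance=distance,
                        prominence=prominence_fraction * value_range)
    return idx, float(min_period_s)


def _refine_quadratic(t: np.ndarray, x: np.ndarray, idx: np.ndarray,
                      half_width_s: float, kind: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Refine extremum times/values by a local quadratic least-squares fit.

    Averages out sampling noise (variance shrinks roughly as 2.25/n over the
    fit window) and, because the window is symmetric, the residual quartic
    bias of the waveform is the same every cycle and cancels in consecutive
    differences.  Falls back to the raw sample where the fit is not convex
    (concave for maxima) or the vertex leaves the window.
    """
    dt = t[1] - t[0]
    w = max(2, int(round(half_width_s / dt)))
    t_out = t[idx].astype(float).copy()
    x_out = x[idx].astype(float).copy()
    for j, i in enumerate(idx):
        lo, hi = max(0, i - w), min(x.size, i + w + 1)
        if hi - lo < 5:
            continue
        tt = t[lo:hi] - t[i]
        a, b, c = np.polyfit(tt, x[lo:hi], 2)
        wants_min = kind == "min"
        if (wants_min and a <= 0) or (not wants_min and a >= 0):
            continue
        tv = -b / (2 * a)
        if abs(tv) > half_width_s:
            continue
        t_out[j] = t[i] + tv
        x_out[j] = c - b * b / (4 * a)
    # refined times must stay strictly increasing; revert any inversions
    bad = np.flatnonzero(np.diff(t_out) <= 0)
    if bad.size:
        t_out, x_out = t[idx].astype(float), x[idx].astype(float)
    return t_out, x_out


def detect_expiration_points(trace: RespiratoryTrace, direction: str,
                             min_period_s: float | None = None,
                             prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
                             sign: int = 1,
                             refine_half_width_s: float | None = None,
                             ) -> ExpirationSeries:
    """Detect the per-cycle end-expiration points of one direction.

    Expiration points are local minima of ``sign * signal`` with
    inter-minimum spacing >= ``min_period_s`` (default: half the
    autocorrelation-estimated cycle) and prominence >=
    ``prominence_fraction`` times the :func:`oscillation_range`; extrema at
    the first/last sample are excluded.  A constant signal yields an empty
    series with ``constant_signal=True``.  ``refine_half_width_s`` enables
    quadratic-vertex refinement of each point (recommended on noisy data;
    pass ``"auto"`` for 0.4x the minimum period).
    """
    x_orig = trace.direction(direction)
    x = sign * x_orig
    idx, min_period = _find_extrema(x, trace.sample_rate_hz, "min",
                                    min_period_s, prominence_fraction)
    if np.ptp(x) == 0:
        return ExpirationSeries(direction, np.array([]), np.array([]),
                                min_period_s=min_period, constant_signal=True)
    if refine_half_width_s == "auto":
        refine_half_width_s = 0.4 * min_period
    if refine_half_width_s and idx.size:
        t_ep, v = _refine_quadratic(trace.time_s, x, idx,
                                    float(refine_half_width_s), "min")
        a_ep = sign * v
    else:
        t_ep, a_ep = trace.time_s[idx], x_orig[idx]
    return ExpirationSeries(direction, t_ep, a_ep, min_period_s=min_period)


def detect_inspiration_peaks(trace: RespiratoryTrace, direction: str,
                             min_period_s: float | None = None,
                             prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
                             sign: int = 1) -> np.ndarray:
    """Sample indices of inspiration peaks (local maxima of ``sign*signal``)."""
    x = sign * trace.direction(direction)
    idx, _ = _find_extrema(x, trace.sample_rate_hz, "max",
                           min_period_s, prominence_fraction)
    return idx


def compute_baseline_drift(series: ExpirationSeries) -> DriftProfile:
    """Per-cycle-pair drift rates ``delta_n`` (mm/s) with summary stats."""
    if len(series) < 2:
        return DriftProfile(series.direction, np.array([]), np.array([]),
                            summary=None)
    dt = np.diff(series.t_ep)
    if np.any(dt <= 0):
        raise ValueError("expiration times must be strictly increasing")
    delta = np.abs(np.diff(series.a_ep)) / dt
    t_mid = (series.t_ep[:-1] + series.t_ep[1:]) / 2.0
    summary = {
        "mean": float(np.mean(delta)),
        "max": float(np.max(delta)),
        "p95": float(np.percentile(delta, 95)),
    }
    return DriftProfile(series.direction, delta, t_mid, summary=summary)


def summarize_drift(profiles: list[DriftProfile],
                    aggregation: str = "mean") -> dict:
    """Aggregate drift profiles per direction.

    For each direction present, reports the mean of per-profile means and the
    max of per-profile maxima; ``aggregation`` selects which of the two is the
    headline ``value``.  Directions with only empty profiles are flagged.
    """
    if not profiles:
        raise ValueError("at least one DriftProfile is required")
    if aggregation not in ("mean", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    out: dict = {"aggregation": aggregation}
    for direction in DIRECTIONS:
        dir_profiles = [p for p in profiles if p.direction == direction]
        if not dir_profiles:
            continue
        nonempty = [p for p in dir_profiles if not p.empty]
        if not nonempty:
            out[direction] = {"empty": True, "n_profiles": len(dir_profiles)}
            continue
        means = np.array([p.summary["mean"] for p in nonempty])
        maxes = np.array([p.summary["max"] for p in nonempty])
        out[direction] = {
            "empty": False,
            "n_profiles": len(nonempty),
            "mean_of_means": float(means.mean()),
            "max_of_maxes": float(maxes.max()),
            "value": float(means.mean() if aggregation == "mean" else maxes.max()),
        }
    return out


def drift_profile_for_trace(trace: RespiratoryTrace, direction: str,
                            **detect_kwargs) -> DriftProfile:
    """Convenience: detect expiration points and quantify drift in one call."""
    series = detect_expiration_points(trace, direction, **detect_kwargs)
    return compute_baseline_drift(series)
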