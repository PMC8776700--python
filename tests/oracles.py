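"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the extrema scan is an
explicit plateau-aware loop (not scipy.signal.find_peaks), the residual
oracle evaluates the closed-form waveform on a dense time grid, and the
DVH oracle loops over voxels and interpolates order statistics by hand.
"""

from __future__ import annotations

import numpy as np

from respigate.synthetic import WaveformSpec, cycle_structure, evaluate_waveform


def exhaustive_minima(x: np.ndarray, distance: int,
                      prominence_threshold: float) -> np.ndarray:
    """Local minima of ``x`` under spacing/prominence constraints.

    Mirrors the documented contract: plateau midpoints, highest-priority
    (deepest) minima keep their neighbourhood within ``distance``, then a
    prominence floor is applied.  Pure-python scan, no scipy.
    """
    y = -np.asarray(x, dtype=float)
    n = y.size
    cand = []
    i = 1
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                cand.append((i + j) // 2)
                i = j + 1
                continue
        i += 1
    cand_a = np.array(cand, dtype=int)
    if cand_a.size == 0:
        return cand_a
    # spacing: process by decreasing height (deepest minimum first)
    keep = np.ones(cand_a.size, dtype=bool)
    order = np.argsort(y[cand_a])[::-1]
    for oi in order:
        if not keep[oi]:
            continue
        for m in range(cand_a.size):
            if m != oi and keep[m] and abs(cand_a[m] - cand_a[oi]) < distance:
                keep[m] = False
    survivors = cand_a[keep]
    # prominence: height above the higher of the two side bases
    out = []
    for p in survivors:
        lmin = y[p]
        i = p - 1
        while i >= 0 and y[i] <= y[p]:
            lmin = min(lmin, y[i])
            i -= 1
        rmin = y[p]
        i = p + 1
        while i < n and y[i] <= y[p]:
            rmin = min(rmin, y[i])
            i += 1
        if y[p] - max(lmin, rmin) >= prominence_threshold:
            out.append(p)
    return np.array(sorted(out), dtype=int)


def analytic_inspiration_peaks(spec: WaveformSpec) -> np.ndarray:
    """Inspiration-peak times of the noiseless waveform (cycle midpoints)."""
    starts, periods, _ = cycle_structure(spec)
    peaks = starts + periods / 2.0
    return peaks[peaks <= spec.duration_s]


def dense_residual_motion(spec: WaveformSpec, method: str,
                          intervals, gating_direction: str = "cc",
                          n_calibration_cycles: int = 3,
                          oversample: int = 40) -> np.ndarray:
    """Per-cycle in-window position range from a dense-grid evaluation.

    Cycles run inspiration peak to inspiration peak.  Phase gating
    normalises time within each cycle; amplitude gating normalises the
    signal to the dense min/max of the first calibration cycles, with
    intervals touching 0/1 open-ended.  Returns shape ``(n_cycles, 3)``.
    """
    d_idx = {"ap": 0, "cc": 1, "lr": 2}[gating_direction]
    peaks = analytic_inspiration_peaks(spec)
    dt = 1.0 / (spec.sample_rate_hz * oversample)
    if method == "amplitude":
        t_cal = np.arange(peaks[0], peaks[n_calibration_cycles], dt)
        cal = evaluate_waveform(spec, t_cal)[:, d_idx]
        a_min, a_max = cal.min(), cal.max()
    per_cycle = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        t = np.arange(p0, p1, dt)
        pos = evaluate_waveform(spec, t)
        if method == "phase":
            values = (t - p0) / (p1 - p0)
        else:
            values = (pos[:, d_idx] - a_min) / (a_max - a_min)
        on = np.zeros(t.size, dtype=bool)
        for lo, hi in intervals:
            lo_eff = -np.inf if (method == "amplitude" and lo == 0.0) else lo
            hi_eff = np.inf if (method == "amplitude" and hi == 1.0) else hi
            on |= (values >= lo_eff) & (values <= hi_eff)
        if on.sum() < 2:
            per_cycle.append(np.zeros(3))
        else:
            sel = pos[on]
            per_cycle.append(sel.max(axis=0) - sel.min(axis=0))
    return np.array(per_cycle)


def max_slope_mm_per_s(spec: WaveformSpec, oversample: int = 40) -> float:
    """Largest position rate of change of the noiseless waveform."""
    dt = 1.0 / (spec.sample_rate_hz * oversample)
    t = np.arange(0.0, spec.duration_s, dt)
    pos = evaluate_waveform(spec, t)
    return float(np.max(np.abs(np.diff(pos, axis=0))) / dt)


def brute_dvh(dose_gy: np.ndarray, coords, center, radius: float,
              edges: np.ndarray):
    """Voxel-exhaustive DVH: explicit loop over voxel centers.

    Returns ``(volume_fraction_at_edges, quantile_fn)`` where the quantile
    function interpolates order statistics linearly at position
    ``(n - 1) * q`` (the standard empirical-quantile convention).
    """
    doses = []
    for i, xi in enumerate(coords[0]):
        for j, yj in enumerate(coords[1]):
            for k, zk in enumerate(coords[2]):
                dx = xi - center[0]
                dy = yj - center[1]
                dz = zk - center[2]
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    doses.append(dose_gy[i, j, k])
    doses = np.sort(np.array(doses))
    n = doses.size
    vf = np.array([(doses >= e).sum() / n for e in edges])

    def quantile(q: float) -> float:
        pos = (n - 1) * q
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return float(doses[lo] * (1 - frac) + doses[hi] * frac)

    return vf, quantile
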