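"""Gating windows, beam-on masks and residual motion."""

import numpy as np
import pytest

from conftest import make_spec
from oracles import dense_residual_motion, max_slope_mm_per_s
from respigate.gating import (AMPLITUDE_WINDOWS, PHASE_WINDOWS, GatingError,
                              GatingWindowSpec, METHODS, PHASES, assign_phase,
                              calibrate_amplitude, compare_gating_methods,
                              compute_gating_mask, compute_residual_motion,
                              prepare_gating, residual_difference)
from respigate.synthetic import generate_trace
from respigate.trace import RespiratoryTrace


class TestWindowSpec:
    def test_defaults_match_standard_settings(self):
        assert GatingWindowSpec.default("phase", "expiration").intervals == \
            ((0.35, 0.65),)
        assert GatingWindowSpec.default("amplitude", "inspiration").intervals == \
            ((0.70, 1.0),)

    @pytest.mark.parametrize("intervals", [
        ((0.5, 0.4),), ((-0.1, 0.5),), ((0.0, 0.5), (0.4, 0.8))])
    def test_bad_intervals_rejected(self, intervals):
        with pytest.raises(ValueError):
            GatingWindowSpec("phase", "expiration", intervals)


class TestPhaseAssignment:
    def test_phase_zero_at_anchor_and_trough_at_half(self, clean_trace):
        a = assign_phase(clean_trace)
        anchors = a.anchor_indices
        np.testing.assert_allclose(a.phase_fraction[anchors[:-1]], 0.0)
        cc = clean_trace.direction("cc")
        in_cycle = a.in_cycle
        troughs = np.flatnonzero(in_cycle & (cc < 1e-9))
        dt_phase = 1.0 / (3.0 * clean_trace.sample_rate_hz)
        np.testing.assert_allclose(a.phase_fraction[troughs], 0.5,
                                   atol=dt_phase)

    def test_irregular_cycles_each_map_to_unit_interval(self):
        tr = generate_trace(make_spec(period_cv=0.25, seed=8))
        a = assign_phase(tr)
        pf = a.phase_fraction[a.in_cycle]
        assert pf.min() >= 0.0 and pf.max() < 1.0
        # phase resets at every anchor
        for k in range(a.n_cycles):
            sel = a.cycle_index == k
            assert a.phase_fraction[sel][0] == 0.0

    def test_out_of_cycle_samples_flagged(self, clean_trace):
        a = assign_phase(clean_trace)
        before = np.arange(clean_trace.n_samples) < a.anchor_indices[0]
        assert np.all(a.cycle_index[before] == -1)
        assert np.all(np.isnan(a.phase_fraction[before]))

    def test_too_few_peaks_raises_naming_trace(self):
        t = np.arange(60) / 30.0
        x = np.column_stack([t * 0, np.sin(2 * np.pi * t / 10.0), t * 0])
        tr = RespiratoryTrace(t, x, meta={"trace_id": "short_one"})
        with pytest.raises(GatingError, match="short_one"):
            assign_phase(tr)


class TestAmplitudeCalibration:
    def test_calibration_of_clean_trace_is_full_range(self, clean_trace):
        ctx = prepare_gating(clean_trace)
        assert ctx.calibration == pytest.approx((0.0, 10.0), abs=1e-9)

    def test_calibration_ignores_later_cycles(self, drifting_trace):
        """Bounds are fixed from the first three cycles; the drifted tail
        (baseline falls 0.3 mm/s) does not lower a_min."""
        ctx = prepare_gating(drifting_trace)
        a_min, a_max = ctx.calibration
        assert a_min > drifting_trace.direction("cc").min() + 10.0
        late_troughs = ctx.assignment.amplitude_fraction[
            drifting_trace.time_s > 80.0]
        assert late_troughs.min() < 0.0  # unclipped below the range

    def test_insufficient_cycles_error(self):
        tr = generate_trace(make_spec(duration_s=7.0))
        with pytest.raises(GatingError, match="calibration"):
            prepare_gating(tr, n_calibration_cycles=3)


class TestMasks:
    def test_full_phase_window_covers_all_in_cycle_samples(self, clean_trace):
        ctx = prepare_gating(clean_trace)
        w = GatingWindowSpec("phase", "expiration", ((0.0, 1.0),))
        mask = compute_gating_mask(ctx.assignment, w)
        assert np.array_equal(mask.on, ctx.assignment.in_cycle)
        assert mask.duty_cycle == pytest.approx(
            ctx.assignment.in_cycle.mean())

    @pytest.mark.parametrize("phase", PHASES)
    def test_phase_duty_cycle_equals_window_width(self, clean_trace, phase):
        """Uniform phase speed: in-cycle duty equals the window width to
        within 2 samples per cycle."""
        ctx = prepare_gating(clean_trace)
        w = GatingWindowSpec.default("phase", phase)
        mask = compute_gating_mask(ctx.assignment, w)
        n_in = ctx.assignment.in_cycle.sum()
        samples_per_cycle = 3.0 * clean_trace.sample_rate_hz
        assert mask.on.sum() / n_in == pytest.approx(
            w.total_width, abs=2.0 / samples_per_cycle)

    def test_amplitude_interior_window_bounds_are_exact(self, drifting_trace):
        """Beam-on positions of an interior amplitude window stay inside the
        mapped calibration levels, exactly."""
        ctx = prepare_gating(drifting_trace)
        a_min, a_max = ctx.calibration
        w = GatingWindowSpec.default("amplitude", "transition")  # [0.35, 0.65]
        mask = compute_gating_mask(ctx.assignment, w)
        cc = drifting_trace.direction("cc")[mask.on]
        span = a_max - a_min
        assert cc.min() >= a_min + 0.35 * span
        assert cc.max() <= a_min + 0.65 * span

    def test_open_ended_window_keeps_drifted_troughs(self, drifting_trace):
        """Expiration window [0, 0.30]: troughs that drift below the
        calibration minimum stay beam-on (open lower end), but are cut in
        strict-bounds mode."""
        ctx = prepare_gating(drifting_trace)
        w = GatingWindowSpec.default("amplitude", "expiration")
        open_mask = compute_gating_mask(ctx.assignment, w)
        strict_mask = compute_gating_mask(ctx.assignment, w, strict_bounds=True)
        af = ctx.assignment.amplitude_fraction
        assert (open_mask.on & (af < 0)).any()
        assert not (strict_mask.on & (af < 0)).any()
        assert strict_mask.on.sum() < open_mask.on.sum()

    def test_static_trace_gates_every_window(self):
        t = np.arange(300) / 30.0
        tr = RespiratoryTrace(t, np.full((300, 3), 2.0))
        ctx = prepare_gating(tr)
        assert ctx.assignment.static
        for method in METHODS:
            for phase in PHASES:
                mask = compute_gating_mask(
                    ctx.assignment, GatingWindowSpec.default(method, phase))
                assert mask.on.all()


class TestResidualMotion:
    def test_all_on_mask_recovers_full_amplitude(self, clean_trace):
        ctx = prepare_gating(clean_trace)
        w = GatingWindowSpec("phase", "expiration", ((0.0, 1.0),))
        mask = compute_gating_mask(ctx.assignment, w)
        res = compute_residual_motion(clean_trace, mask,
                                      ctx.assignment.cycle_index)
        np.testing.assert_allclose(res.mean_mm, [4.0, 10.0, 2.5], rtol=1e-3)

    def test_expiration_windows_match_closed_forms(self, clean_trace):
        """Phase expiration selects the trough +/- 15% of the cycle
        (range A(1 - cos(0.3 pi))/2); amplitude expiration selects the
        bottom 30% of the calibration range (range 0.30 A)."""
        quantum = max_slope_mm_per_s(make_spec()) / clean_trace.sample_rate_hz
        df = compare_gating_methods(clean_trace)
        ph = df[(df.method == "phase") & (df.phase == "expiration")].iloc[0]
        am = df[(df.method == "amplitude") & (df.phase == "expiration")].iloc[0]
        assert ph.cc_mm == pytest.approx(10.0 * (1 - np.cos(0.3 * np.pi)) / 2,
                                         abs=2 * quantum)
        assert am.cc_mm == pytest.approx(3.0, abs=2 * quantum)

    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("phase", PHASES)
    def test_matches_dense_grid_oracle(self, method, phase):
        """Per-cycle in-window ranges match a dense-grid evaluation of the
        analytic waveform within the one-sample position quantum, for every
        method x phase window, stationary and drifted."""
        for spec in (make_spec(duration_s=45.0),
                     make_spec(duration_s=45.0,
                               drift_rate_mm_per_s=(-0.1, -0.25, -0.05))):
            tr = generate_trace(spec)
            ctx = prepare_gating(tr)
            w = GatingWindowSpec.default(method, phase)
            mask = compute_gating_mask(ctx.assignment, w)
            res = compute_residual_motion(tr, mask, ctx.assignment.cycle_index)
            oracle = dense_residual_motion(spec, method, w.intervals)
            quantum = max_slope_mm_per_s(spec) / spec.sample_rate_hz
            n = min(len(oracle), res.per_cycle_range_mm.shape[0])
            assert n >= 10
            np.testing.assert_allclose(res.per_cycle_range_mm[:n],
                                       oracle[:n], atol=2 * quantum)

    def test_widening_window_never_decreases_residual(self, clean_trace):
        ctx = prepare_gating(clean_trace)
        widths = [0.1, 0.2, 0.3, 0.5, 0.8, 1.0]
        prev = -1.0
        for width in widths:
            w = GatingWindowSpec("phase", "expiration",
                                 ((0.5 - width / 2, 0.5 + width / 2),))
            mask = compute_gating_mask(ctx.assignment, w)
            res = compute_residual_motion(clean_trace, mask,
                                          ctx.assignment.cycle_index)
            assert res.mean_mm[1] >= prev
            prev = res.mean_mm[1]

    def test_residual_norm_between_max_and_sum(self, drifting_trace):
        df = compare_gating_methods(drifting_trace)
        for _, row in df.iterrows():
            means = np.array([row.ap_mm, row.cc_mm, row.lr_mm])
            assert row.residual_3d_mm <= means.sum() + 1e-9
            assert row.residual_3d_mm >= means.max() - 1e-9

    def test_all_off_mask_warns_with_zero_residual(self):
        """A strongly drifted trace with strict amplitude bounds: the
        inspiration window empties out; residual is zero and flagged."""
        spec = make_spec(duration_s=90.0,
                         drift_rate_mm_per_s=(0.0, -0.5, 0.0))
        tr = generate_trace(spec)
        ctx = prepare_gating(tr)
        w = GatingWindowSpec.default("amplitude", "inspiration")
        mask = compute_gating_mask(ctx.assignment, w, strict_bounds=True)
        late = tr.time_s > 40.0
        assert not (mask.on & late).any()  # drifted out of the fixed window

    def test_phase_spread_exceeds_amplitude_spread_under_drift(self):
        """Under strong drift the in-window position spread of phase gating
        exceeds the amplitude-gating spread by at least the net drift the
        amplitude window avoids."""
        spec = make_spec(duration_s=120.0,
                         drift_rate_mm_per_s=(0.0, 0.4, 0.0))
        tr = generate_trace(spec)
        ctx = prepare_gating(tr)
        cc = tr.direction("cc")
        w_ph = GatingWindowSpec.default("phase", "transition")
        w_am = GatingWindowSpec.default("amplitude", "transition")
        on_ph = compute_gating_mask(ctx.assignment, w_ph).on
        on_am = compute_gating_mask(ctx.assignment, w_am).on
        spread_ph = np.ptp(cc[on_ph])
        spread_am = np.ptp(cc[on_am])
        a_min, a_max = ctx.calibration
        assert spread_am <= 0.30 * (a_max - a_min) + 0.5
        assert spread_ph > spread_am + 0.5 * 0.4 * 120.0


class TestComparisonTable:
    def test_table_layout_and_difference(self, drifting_trace):
        df = compare_gating_methods(drifting_trace)
        assert len(df) == 6
        assert set(df.method) == set(METHODS)
        assert set(df.phase) == set(PHASES)
        diff = residual_difference(df)
        assert len(diff) == 3
        merged = diff.set_index("phase")
        for phase in PHASES:
            ph = df[(df.method == "phase") & (df.phase == phase)].iloc[0]
            am = df[(df.method == "amplitude") & (df.phase == phase)].iloc[0]
            assert merged.loc[phase, "residual_3d_mm"] == pytest.approx(
                ph.residual_3d_mm - am.residual_3d_mm)
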