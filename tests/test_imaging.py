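"""Imaging pipeline: registration, extraction, ΔF/F, averaging, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from laminakit import imaging, stimuli
from laminakit.imaging import (
    ImageStack,
    RoiTrace,
    RoiTraceSet,
    ab_responses,
    compute_dff,
    edge_response,
    extract_traces,
    filter_rois,
    plateau_responses,
    register_stack,
    response_table,
    staircase_step_response,
    trial_average,
)
from laminakit.synthetic_data import LmcParams, default_masks, simulate_lmc, simulate_movie


def _trace_from(values, rate=10.0, **meta):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) / rate
    kw = dict(fly_id="f", roi_id="r", cell_type="custom")
    kw.update(meta)
    return RoiTrace(time=t, raw_f=values, sample_rate=rate, **kw)


class TestRegistration:
    def _movie(self, shifts, noise_sd=0.0, n_frames=50):
        rng = np.random.default_rng(3)
        t = np.arange(n_frames) / 10.0
        traces = RoiTraceSet(
            [
                RoiTrace("f", f"roi{k}", "custom", t, 4 + rng.random(n_frames), 10.0)
                for k in range(3)
            ]
        )
        masks = default_masks((48, 48), 3)
        stack, truth = simulate_movie(
            traces, (48, 48), masks, shifts=shifts, noise_sd=noise_sd
        )
        return stack, truth, masks, traces

    def test_aligned_stack_has_zero_shifts(self):
        stack, truth, _, _ = self._movie(shifts=None)
        _, shifts = register_stack(stack)
        assert np.array_equal(shifts, np.zeros_like(shifts))

    def test_planted_shifts_recovered_exactly_at_zero_noise(self):
        n = 60
        rng = np.random.default_rng(11)
        shifts = np.zeros((n, 2), dtype=int)
        shifts[30:] = rng.integers(-5, 6, size=(n - 30, 2))  # reference frames clean
        stack, truth, _, _ = self._movie(shifts=shifts, n_frames=n)
        aligned, detected = register_stack(stack)
        assert np.array_equal(detected, shifts)

    def test_registration_round_trip_restores_frames(self):
        n = 40
        shifts = np.zeros((n, 2), dtype=int)
        shifts[35:] = [[3, -2]] * 5
        stack, truth, masks, traces = self._movie(shifts=shifts, n_frames=n)
        aligned, _ = register_stack(stack)
        clean, _, _, _ = self._movie(shifts=None, n_frames=n)
        assert np.allclose(aligned.frames, clean.frames)

    def test_pure_noise_frames_do_not_crash(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.random((10, 32, 32)), 10.0)
        _, shifts = register_stack(stack, max_shift=4)
        assert np.abs(shifts).max() <= 4

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(np.empty((0, 8, 8)), 10.0)


class TestTiffRoundTrip:
    def test_save_load_preserves_frames_and_rate(self, tmp_path, rng):
        stack = ImageStack(rng.random((6, 16, 16)), 12.5)
        path = tmp_path / "movie.tif"
        imaging.save_stack(stack, path)
        back = imaging.load_stack(path)
        assert back.frame_rate == pytest.approx(12.5)
        assert np.allclose(back.frames, stack.frames, atol=1e-6)


class TestExtraction:
    def test_uniform_frame_background_subtraction(self):
        frames = np.full((5, 20, 20), 7.0)
        frames[:, 15:, :] = 2.0  # background strip
        roi = np.zeros((20, 20), dtype=bool)
        roi[2:5, 2:5] = True
        bg = np.zeros((20, 20), dtype=bool)
        bg[16:19, 2:18] = True
        masks = imaging.RoiMask([roi], bg)
        traces = extract_traces(ImageStack(frames, 10.0), masks)
        assert np.allclose(traces.traces[0].raw_f, 5.0)

    def test_background_equal_to_roi_gives_zero(self):
        frames = np.random.default_rng(0).random((5, 16, 16))
        m = np.zeros((16, 16), dtype=bool)
        m[2:6, 2:6] = True
        masks = imaging.RoiMask([m], m.copy())
        traces = extract_traces(ImageStack(frames, 10.0), masks)
        assert np.allclose(traces.traces[0].raw_f, 0.0)


class TestDff:
    def test_constant_trace_whole_mean_gives_zero(self):
        tr = compute_dff(_trace_from(np.full(20, 4.0)))
        assert np.allclose(tr.dff, 0.0)

    def test_arithmetic_example(self):
        tr = compute_dff(_trace_from([1.0, 3.0]))
        assert np.allclose(tr.dff, [-0.5, 0.5])

    def test_adaptation_window_mode(self):
        vals = np.concatenate([np.full(30, 2.0), np.full(30, 4.0)])
        tr = compute_dff(
            _trace_from(vals, rate=1.0), f0_mode="adaptation_mean", window=(0.0, 30.0)
        )
        assert np.allclose(tr.dff[:30], 0.0)
        assert np.allclose(tr.dff[30:], 1.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compute_dff(_trace_from([-1.0, 1.0]))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(0.1, 100.0))
    def test_dff_invariant_to_positive_rescaling(self, c):
        rng = np.random.default_rng(7)
        vals = 5.0 + rng.random(40)
        a = compute_dff(_trace_from(vals))
        b = compute_dff(_trace_from(c * vals))
        assert np.allclose(a.dff, b.dff)


class TestTrialAverage:
    def test_constant_trace_averages_constant(self, flashes):
        n = int(flashes.total_duration * 13)
        tr = compute_dff(_trace_from(np.full(n, 3.0), rate=13.0))
        avg = trial_average(tr, flashes)
        for ep in avg.epochs.values():
            assert np.allclose(ep.mean, 0.0)
            assert avg.sample_rate == 10.0

    def test_single_repetition_is_interpolated_trace(self):
        cal = stimuli.Calibration.projector(1.0)
        proto = stimuli.StimulusProtocol(
            name="one",
            epochs=[stimuli.Epoch("e", "flash", 2.0, {"level": 0.5})],
            presentation_order=[0],
            calibration=cal,
        )
        vals = np.linspace(0.0, 1.0, 21)
        tr = _trace_from(vals, rate=10.0)
        avg = trial_average(tr, proto)
        assert np.allclose(avg["e"].mean, np.interp(avg["e"].tau, tr.time, vals))

    def test_symmetric_noise_cancels_exactly(self):
        cal = stimuli.Calibration.projector(1.0)
        proto = stimuli.StimulusProtocol(
            name="two",
            epochs=[stimuli.Epoch("e", "flash", 1.0, {"level": 0.5})],
            presentation_order=[0, 0],
            calibration=cal,
        )
        rng = np.random.default_rng(0)
        noise = rng.normal(size=10)
        vals = np.concatenate([1.0 + noise, 1.0 - noise])
        tr = _trace_from(vals, rate=10.0)
        avg = trial_average(tr, proto)
        assert np.allclose(avg["e"].mean, 1.0)
        assert avg["e"].n_trials == 2


class TestFilterRois:
    def test_normal_polarity_kept_offscreen_rejected(self, flashes):
        params = LmcParams.preset("L1", p_offscreen=0.0, noise_sd=0.01)
        good = simulate_lmc(params, flashes, n_flies=1, rois_per_fly=4, seed=1)
        inv = simulate_lmc(
            LmcParams.preset("L1", polarity=+1, p_offscreen=0.0, noise_sd=0.01),
            flashes,
            n_flies=1,
            rois_per_fly=4,
            seed=2,
        )
        all_traces = RoiTraceSet(
            [compute_dff(t) for t in list(good) + list(inv.traces)]
        )
        kept, report = filter_rois(all_traces, flashes)
        assert report["kept"].tolist() == [True] * 4 + [False] * 4

    def test_constant_trace_rejected_and_flagged(self, flashes):
        n = int(flashes.total_duration * 13)
        tr = _trace_from(np.full(n, 2.0), rate=13.0)
        tr.dff = np.zeros(n)
        kept, report = filter_rois(RoiTraceSet([tr]), flashes)
        assert len(kept) == 0
        assert np.isnan(report["spearman_rho"].iloc[0])


class TestResponseMetrics:
    def test_staircase_step_arithmetic(self):
        # planted trace: 0.2 during the brightest epoch tail, bump of 0.8 in
        # the first down-step epoch
        staircase = stimuli.build_staircase(n_repeats=1)
        rate = 10.0
        n = int(staircase.total_duration * rate)
        vals = np.zeros(n)
        sched = staircase.schedule()
        prev = next(s for s in sched if s.epoch.label == "stair04")
        step = next(s for s in sched if s.epoch.label == "stair05")
        t = np.arange(n) / rate
        vals[(t >= prev.t_start) & (t < prev.t_end)] = 0.2
        vals[np.searchsorted(t, step.t_start + 1.0)] = 0.8
        tr = _trace_from(vals, rate=rate)
        tr.dff = vals
        avg = trial_average(tr, staircase)
        steps = staircase_step_response(avg, staircase)
        first = steps.loc[steps["step"] == "stair05", "response"].iloc[0]
        assert first == pytest.approx(0.8 - 0.2, abs=1e-6)

    def test_l2_step_response_increases_with_weber_magnitude(self, staircase):
        params = LmcParams.preset("L2", noise_sd=0.0, p_offscreen=0.0)
        traces = simulate_lmc(params, staircase, n_flies=1, rois_per_fly=1, seed=0)
        tr = compute_dff(traces.traces[0])
        steps = staircase_step_response(trial_average(tr, staircase), staircase)
        ordered = steps.sort_values("contrast_magnitude")["response"].to_numpy()
        assert (np.diff(ordered) > 0).all()

    def test_plateau_subtract_highest_zeroes_top_level(self, flashes):
        params = LmcParams.preset("L1", noise_sd=0.0, p_offscreen=0.0)
        tr = compute_dff(simulate_lmc(params, flashes, 1, 1, seed=0).traces[0])
        plate = plateau_responses(
            trial_average(tr, flashes), flashes, subtract_highest=True
        )
        top = plate.loc[plate["luminance"].idxmax(), "plateau"]
        assert top == 0.0

    def test_ab_peaks_equal_for_transient_only_cell(self):
        proto = stimuli.build_ab_protocol(seed=4)
        params = LmcParams.preset("L2", noise_sd=0.0, p_offscreen=0.0)
        tr = compute_dff(
            simulate_lmc(params, proto, 1, 1, seed=0).traces[0],
            f0_mode="adaptation_mean",
            window=(0.0, 30.0),
        )
        resp = ab_responses(trial_average(tr, proto), proto)
        b_peaks = resp.loc[resp["step_kind"] == "B", "peak"].to_numpy()
        # every B step is the same -25% Weber contrast
        assert np.ptp(b_peaks) < 0.05 * np.abs(b_peaks).mean()

    def test_ab_sustained_monotone_in_luminance_for_l1(self):
        proto = stimuli.build_ab_protocol(seed=4)
        params = LmcParams.preset("L1", noise_sd=0.0, p_offscreen=0.0)
        tr = compute_dff(
            simulate_lmc(params, proto, 1, 1, seed=0).traces[0],
            f0_mode="adaptation_mean",
            window=(0.0, 30.0),
        )
        resp = ab_responses(trial_average(tr, proto), proto)
        a_rows = resp[resp["step_kind"] == "A"].sort_values("luminance")
        # darker A steps leave a larger sustained depolarization
        assert (np.diff(a_rows["sustained"].to_numpy()) < 0).all()

    def test_edge_response_measures_planted_deflection(self):
        proto = stimuli.build_edge_protocol(
            "ON", n_trials=2, seed=0, iti_duration=4.0
        )
        rate = 10.0
        n = int(proto.total_duration * rate)
        t = np.arange(n) / rate
        vals = np.zeros(n)
        target = next(
            s for s in proto.schedule() if s.epoch.kind == "edge_motion"
        )
        vals[np.searchsorted(t, target.t_start + 0.4)] = -0.7
        tr = _trace_from(vals, rate=rate)
        tr.dff = vals
        resp = edge_response(trial_average(tr, proto), proto)
        row = resp[resp["epoch"] == target.epoch.label].iloc[0]
        n_reps = len(proto.occurrences(target.epoch.label))
        assert row["response"] == pytest.approx(0.7 / n_reps, abs=1e-6)

    def test_l1_edge_response_scales_with_luminance(self):
        proto = stimuli.build_edge_protocol("ON", n_trials=2, seed=0, iti_duration=4.0)
        params = LmcParams.preset("L1", noise_sd=0.0, p_offscreen=0.0)
        tr = compute_dff(simulate_lmc(params, proto, 1, 1, seed=0).traces[0])
        resp = edge_response(trial_average(tr, proto), proto)
        ordered = resp.sort_values("edge_luminance")["response"].to_numpy()
        assert ordered[-1] > ordered[0]
        assert np.corrcoef(np.arange(len(ordered)), ordered)[0, 1] > 0.9

    def test_response_table_carries_provenance(self, flashes):
        params = LmcParams.preset("L1", p_offscreen=0.0)
        traces = simulate_lmc(params, flashes, n_flies=2, rois_per_fly=2, seed=0)
        table = response_table(traces, flashes, "plateau")
        assert set(table["fly_id"]) == {"fly0", "fly1"}
        assert len(table) == 4 * 5  # rois x luminance levels
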