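"""Escape-responsiveness slope tests and time warping to the event template."""

import numpy as np
import pytest

from tonicpag import escape_response as er
from tonicpag.escape_response import (
    TEMPLATE_EVENTS,
    WarpTemplate,
    baseline_subtract,
    build_template,
    escape_active_test,
    mean_response,
    repair_artifact,
    warp_trace,
)
from tonicpag.spiketrain import InsufficientDataError

FS = 30.0


def template_from_times(times, grid_rate=30.0):
    return WarpTemplate(TEMPLATE_EVENTS, np.asarray(times, float), grid_rate)


STD_TIMES = [0.0, 0.35, 0.6, 0.9, 2.1, 2.4]


class TestBaselineSubtract:
    def test_constant_trace_zeroed(self):
        out = baseline_subtract(np.full(300, 1.2), FS, stimulus_onset=5.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_shift_by_prestimulus_mean(self):
        x = np.zeros(300)
        x[: int(5 * FS)] = 1.2
        out = baseline_subtract(x, FS, 5.0)
        assert out[0] == pytest.approx(0.0)
        assert out[-1] == pytest.approx(-1.2)

    def test_step_height_preserved(self):
        x = np.zeros(300)
        x[int(5 * FS) :] = 0.8
        out = baseline_subtract(x, FS, 5.0)
        assert out[-1] == pytest.approx(0.8)

    def test_insufficient_prestimulus_raises(self):
        with pytest.raises(InsufficientDataError):
            baseline_subtract(np.zeros(100), FS, stimulus_onset=0.2)


class TestEscapeActive:
    def make_trials(self, n_trials, slope=0.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        trials = []
        for _ in range(n_trials):
            t = np.arange(0, 10, 1 / FS)
            events = {
                "stimulus": 2.0, "reaction": 2.35, "turn": 2.6,
                "run": 2.9, "shelter_entry": 4.1, "escape_stop": 4.4,
            }
            x = np.zeros_like(t)
            if slope:
                esc = (t >= events["run"]) & (t <= events["escape_stop"])
                x[esc] = slope * (t[esc] - events["run"])
                x[t > events["escape_stop"]] = slope * (
                    events["escape_stop"] - events["run"]
                )
            if noise:
                x += rng.normal(0, noise, x.size)
            trials.append((x, events))
        return trials

    def test_zero_traces_not_active(self):
        res = escape_active_test(self.make_trials(5), FS)
        assert not res.escape_active
        assert all(p == 1.0 for p in res.p_values.values())

    def test_ramp_motif_detected_at_run_event(self):
        res = escape_active_test(self.make_trials(10, slope=1.0, noise=0.2, seed=1), FS)
        assert res.escape_active
        assert res.p_values["run"] < res.corrected_alpha

    def test_type_one_error_near_alpha(self):
        """Pure-noise neurons are flagged at roughly the Bonferroni-corrected
        5% rate (binomial band around 0.05 for 300 neurons)."""
        hits = 0
        n = 300
        for seed in range(n):
            res = escape_active_test(
                self.make_trials(8, noise=0.5, seed=10_000 + seed), FS
            )
            hits += res.escape_active
        assert 0.01 <= hits / n <= 0.09

    def test_too_few_trials_raise(self):
        with pytest.raises(InsufficientDataError):
            escape_active_test(self.make_trials(2), FS)

    def test_missing_events_reduce_bonferroni(self):
        trials = []
        for x, events in self.make_trials(5):
            events = {k: events[k] for k in ("stimulus", "reaction")}
            trials.append((x, events))
        res = escape_active_test(trials, FS)
        assert res.bonferroni_m == 2
        assert set(res.skipped_events) == {"turn", "run", "shelter_entry", "escape_stop"}


class TestRepairArtifact:
    def test_no_troughs_identity(self):
        x = np.sin(np.arange(300) / 10)
        np.testing.assert_array_equal(repair_artifact(x, FS, []), x)

    def test_notch_repaired(self):
        t = np.arange(0, 20, 1 / FS)
        clean = np.sin(2 * np.pi * 0.2 * t)
        notched = clean.copy()
        c = int(10 * FS)
        notched[c - 3 : c + 4] -= 3.0
        fixed = repair_artifact(notched, FS, [10.0])
        rms = np.sqrt(np.mean((fixed - clean) ** 2))
        assert rms < 0.1

    def test_two_notches_independent(self):
        t = np.arange(0, 30, 1 / FS)
        clean = 0.5 * np.cos(2 * np.pi * 0.1 * t)
        notched = clean.copy()
        for c_s in (8.0, 20.0):
            c = int(c_s * FS)
            notched[c - 2 : c + 3] -= 2.0
        fixed = repair_artifact(notched, FS, [8.0, 20.0])
        assert np.sqrt(np.mean((fixed - clean) ** 2)) < 0.1

    def test_window_at_edge_raises(self):
        with pytest.raises(ValueError):
            repair_artifact(np.zeros(100), FS, [0.2])


class TestTemplate:
    def test_identical_trials_reproduced(self):
        trial = dict(zip(TEMPLATE_EVENTS, STD_TIMES))
        tmpl = build_template([trial, trial, trial])
        np.testing.assert_allclose(tmpl.template_times, STD_TIMES)

    def test_median_of_three(self):
        trials = []
        for stop in (1.0, 2.0, 3.0):
            times = list(STD_TIMES)
            times[-1] = STD_TIMES[-2] + stop
            trials.append(dict(zip(TEMPLATE_EVENTS, times)))
        tmpl = build_template(trials)
        assert tmpl.template_times[-1] == pytest.approx(STD_TIMES[-2] + 2.0)

    def test_per_event_medians_exact(self):
        rng = np.random.default_rng(2)
        trials = []
        for _ in range(7):
            times = np.sort(np.cumsum(rng.uniform(0.1, 0.8, 6)))
            times -= times[0]
            trials.append(dict(zip(TEMPLATE_EVENTS, times)))
        tmpl = build_template(trials)
        stacked = np.array([[tr[e] for e in TEMPLATE_EVENTS] for tr in trials])
        np.testing.assert_allclose(tmpl.template_times, np.median(stacked, axis=0))

    def test_incomplete_trials_ignored(self):
        full = dict(zip(TEMPLATE_EVENTS, STD_TIMES))
        partial = {"stimulus": 0.0, "reaction": 0.3}
        tmpl = build_template([partial, full])
        np.testing.assert_allclose(tmpl.template_times, STD_TIMES)
        with pytest.raises(InsufficientDataError):
            build_template([partial])

    def test_tail_and_grid(self):
        tmpl = template_from_times(STD_TIMES)
        assert tmpl.grid[-1] <= STD_TIMES[-1] + 2.0 + 1e-9
        assert tmpl.grid[-1] >= STD_TIMES[-1] + 2.0 - 1 / tmpl.grid_rate


class TestWarp:
    def test_identity_warp(self):
        tmpl = template_from_times(STD_TIMES)
        x = np.sin(np.arange(0, 10, 1 / FS))
        trial_events = dict(zip(TEMPLATE_EVENTS, np.array(STD_TIMES) + 3.0))
        out = warp_trace(x, FS, trial_events, tmpl)
        grid_t = tmpl.grid + 3.0
        expected = np.interp(grid_t, np.arange(x.size) / FS, x)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_uniformly_slower_trial(self):
        # trial runs 2x slower: value at template time t comes from trial 2t
        tmpl = template_from_times(STD_TIMES)
        fs = 300.0
        t = np.arange(0, 20, 1 / fs)
        x = t.copy()  # linear ramp: interpolation is exact
        trial_events = dict(zip(TEMPLATE_EVENTS, 2.0 * np.asarray(STD_TIMES)))
        out = warp_trace(x, fs, trial_events, tmpl)
        inside = tmpl.grid <= STD_TIMES[-1]
        np.testing.assert_allclose(out[inside], 2.0 * tmpl.grid[inside], atol=1e-9)

    def test_anchor_values_preserved(self):
        tmpl = template_from_times(STD_TIMES)
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 600)
        trial_times = np.array([1.0, 1.5, 1.7, 2.2, 4.0, 4.5])
        trial_events = dict(zip(TEMPLATE_EVENTS, trial_times))
        out = warp_trace(x, FS, trial_events, tmpl)
        for anchor_t, trial_t in zip(STD_TIMES, trial_times):
            idx = anchor_t * tmpl.grid_rate
            if abs(idx - round(idx)) < 1e-9:  # anchor on the grid
                got = out[int(round(idx))]
                want = np.interp(trial_t, np.arange(x.size) / FS, x)
                assert got == pytest.approx(want, abs=1e-9)

    def test_idempotence_on_grid_aligned_input(self):
        tmpl = template_from_times([0.0, 0.3, 0.6, 0.9, 2.1, 2.4])
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, tmpl.grid.size)
        events = dict(zip(TEMPLATE_EVENTS, tmpl.template_times))
        once = warp_trace(x, tmpl.grid_rate, events, tmpl)
        twice = warp_trace(once, tmpl.grid_rate, events, tmpl)
        np.testing.assert_allclose(once, x, atol=1e-9)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_out_of_order_events_raise(self):
        tmpl = template_from_times(STD_TIMES)
        bad = dict(zip(TEMPLATE_EVENTS, [0.0, 0.5, 0.4, 0.9, 2.0, 2.4]))
        with pytest.raises(ValueError):
            warp_trace(np.zeros(300), FS, bad, tmpl)


class TestMeanResponse:
    def _trials(self, n, amp, noise, seed, outcome="escape"):
        rng = np.random.default_rng(seed)
        trials = []
        for _ in range(n):
            t = np.arange(0, 10, 1 / FS)
            events = dict(zip(TEMPLATE_EVENTS, np.asarray(STD_TIMES) + 2.0))
            if outcome == "fail":
                events = {k: events[k] for k in ("stimulus", "reaction")}
            x = np.zeros_like(t)
            if amp and outcome == "escape":
                run, stop = events["run"], events["escape_stop"]
                m = (t >= run) & (t <= stop)
                x[m] = amp * (t[m] - run) / (stop - run)
            x += rng.normal(0, noise, x.size) if noise else 0.0
            trials.append((x, events, outcome))
        return trials

    def test_single_trial_mean_is_that_trial(self):
        tmpl = template_from_times(STD_TIMES)
        trials = self._trials(1, amp=1.0, noise=0.0, seed=0)
        res = mean_response(trials, FS, tmpl)
        w = warp_trace(trials[0][0], FS, trials[0][1], tmpl)
        np.testing.assert_allclose(res.mean_escape, w)

    def test_ramp_window_mean_positive_unmod_near_zero(self):
        tmpl = template_from_times(STD_TIMES)
        ramp = mean_response(self._trials(10, 1.5, 0.3, 1), FS, tmpl)
        flat = mean_response(self._trials(10, 0.0, 0.3, 2), FS, tmpl)
        assert ramp.window_mean_escape > 0.3
        se = 0.3 / np.sqrt(10)
        assert abs(flat.window_mean_escape) < 2 * se

    def test_fail_trials_carry_no_modulation(self):
        tmpl = template_from_times(STD_TIMES)
        trials = self._trials(6, 1.5, 0.0, 3) + self._trials(
            4, 1.5, 0.0, 4, outcome="fail"
        )
        res = mean_response(trials, FS, tmpl)
        assert res.n_escape == 6 and res.n_fail == 4
        assert res.window_mean_escape > 0.3
        assert res.window_mean_fail == pytest.approx(0.0, abs=1e-9)

    def test_no_matching_trials_is_missing(self):
        tmpl = template_from_times(STD_TIMES)
        res = mean_response(self._trials(3, 1.0, 0.0, 5), FS, tmpl)
        assert res.mean_fail is None and res.window_mean_fail is None


def test_event_times_csv(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {
            "trial_id": ["t1", "t1", "t2"],
            "event_name": ["stimulus", "reaction", "stimulus"],
            "time_s": [1.0, 1.3, 50.0],
        }
    )
    path = tmp_path / "events.csv"
    df.to_csv(path, index=False)
    events = er.read_event_times_csv(path)
    assert events["t1"] == {"stimulus": 1.0, "reaction": 1.3}


def test_warped_h5_roundtrip(tmp_path):
    import h5py

    tmpl = template_from_times(STD_TIMES)
    warped = np.random.default_rng(0).normal(size=(4, tmpl.grid.size))
    path = tmp_path / "warped.h5"
    er.write_warped_h5(warped, tmpl, path)
    with h5py.File(path) as f:
        np.testing.assert_array_equal(f["warped"][...], warped)
        np.testing.assert_allclose(f["template_times"][...], STD_TIMES)
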