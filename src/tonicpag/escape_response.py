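"""Escape-responsiveness testing and time warping to a median event template.

Escape trials share a stereotyped event sequence (stimulus -> reaction ->
turn -> run -> shelter entry -> escape stop) with variable inter-event
timing. To average activity across trials, each trial's z-scored trace is
piecewise-linearly time warped so its event times land on the cohort-median
template (median per-event time relative to stimulus onset, with a 2 s tail
after escape stop, resampled on a uniform 30 Hz grid).

A neuron is "escape active" when, for any behavioural event, the
distribution over trials of local activity slopes (least-squares fit over a
660 ms window starting at the event onset) differs from the distribution of
baseline slopes (the 660 ms immediately preceding stimulus onset), by
two-tailed two-sample t-test with Bonferroni correction across events.

Cable-contact motion artifacts (sharp symmetrical downward deflections) are
repaired by cubic interpolation across +/-500 ms around the annotated
trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .spiketrain import InsufficientDataError

__all__ = [
    "WarpTemplate",
    "EventSlopeTest",
    "TEMPLATE_EVENTS",
    "baseline_subtract",
    "escape_active_test",
    "repair_artifact",
    "build_template",
    "warp_trace",
    "mean_response",
    "read_event_times_csv",
    "write_warped_h5",
]

#: canonical template event order; "reaction" is the first stimulus-reaction
#: response (startle) and "run" the escape-run onset
TEMPLATE_EVENTS = ("stimulus", "reaction", "turn", "run", "shelter_entry", "escape_stop")
_ALIASES = {"startle": "reaction", "run_start": "run"}

SLOPE_WINDOW_S = 0.66
BASELINE_WINDOW_S = 0.5
TEMPLATE_TAIL_S = 2.0
TEMPLATE_GRID_RATE_HZ = 30.0


def _canonical(events: Mapping[str, float]) -> dict[str, float]:
    return {_ALIASES.get(k, k): float(v) for k, v in events.items()}


@dataclass(frozen=True)
class WarpTemplate:
    """Common escape time base: per-event median times from stimulus onset
    (strictly ascending, starting at 0) plus a 2 s tail, on a uniform grid."""

    event_names: tuple[str, ...]
    template_times: np.ndarray  # s, relative to stimulus onset
    grid_rate: float
    tail: float = TEMPLATE_TAIL_S

    def __post_init__(self) -> None:
        times = np.asarray(self.template_times, dtype=float)
        object.__setattr__(self, "template_times", times)
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("template times must start at 0 and strictly ascend")

    @property
    def grid(self) -> np.ndarray:
        end = self.template_times[-1] + self.tail
        n = int(np.floor(end * self.grid_rate + 1e-9)) + 1
        return np.arange(n) / self.grid_rate

    def anchor_time(self, event: str) -> float:
        event = _ALIASES.get(event, event)
        return float(self.template_times[self.event_names.index(event)])


def baseline_subtract(
    trace: Sequence[float],
    frame_rate: float,
    stimulus_onset: float,
    window_s: float = BASELINE_WINDOW_S,
) -> np.ndarray:
    """Subtract the mean of the ``window_s`` preceding stimulus onset."""
    x = np.asarray(trace, dtype=float)
    i1 = int(round(stimulus_onset * frame_rate))
    i0 = i1 - int(round(window_s * frame_rate))
    if i0 < 0 or i1 > x.size or i1 <= i0:
        raise InsufficientDataError(
            f"need {window_s} s of pre-stimulus data (have {i1 / frame_rate:.3f} s)"
        )
    return x - x[i0:i1].mean()


def _window_slope(x: np.ndarray, frame_rate: float, start_s: float, window_s: float) -> float | None:
    """Least-squares slope of a trace segment; None when the window does not
    fit inside the trace."""
    i0 = int(round(start_s * frame_rate))
    i1 = i0 + int(round(window_s * frame_rate))
    if i0 < 0 or i1 > x.size or i1 - i0 < 2:
        return None
    t = np.arange(i1 - i0) / frame_rate
    return float(np.polyfit(t, x[i0:i1], 1)[0])


@dataclass(frozen=True)
class EventSlopeTest:
    events: tuple[str, ...]
    p_values: dict[str, float]
    slopes: dict[str, np.ndarray] = field(repr=False)
    baseline_slopes: np.ndarray = field(repr=False)
    bonferroni_m: int
    corrected_alpha: float
    escape_active: bool
    skipped_events: tuple[str, ...] = ()


def escape_active_test(
    trials: Sequence[tuple[Sequence[float], Mapping[str, float]]],
    frame_rate: float,
    window_s: float = SLOPE_WINDOW_S,
    alpha: float = 0.05,
) -> EventSlopeTest:
    """Slope-distribution test of escape responsiveness for one neuron.

    ``trials`` is a sequence of ``(baselined trace, event-time map)`` (times
    in trace coordinates, "stimulus" required). Per trial and event a slope
    is fit over ``window_s`` from the event onset; the baseline slope comes
    from the ``window_s`` immediately preceding stimulus onset. Each event's
    slope distribution is compared with the baseline distribution
    (two-tailed two-sample t-test); the Bonferroni factor is the number of
    events actually tested (events whose window never fits are skipped and
    logged). The neuron is escape active when any corrected test is
    significant.
    """
    if len(trials) < 3:
        raise InsufficientDataError("escape_active_test requires at least 3 trials")
    base_slopes: list[float] = []
    per_event: dict[str, list[float]] = {e: [] for e in TEMPLATE_EVENTS}
    for trace, events in trials:
        x = np.asarray(trace, dtype=float)
        ev = _canonical(events)
        stim = ev["stimulus"]
        b = _window_slope(x, frame_rate, stim - window_s, window_s)
        if b is not None:
            base_slopes.append(b)
        for name in TEMPLATE_EVENTS:
            if name in ev:
                s = _window_slope(x, frame_rate, ev[name], window_s)
                if s is not None:
                    per_event[name].append(s)
    if len(base_slopes) < 2:
        raise InsufficientDataError("fewer than 2 baseline slope samples")
    tested = {e: np.asarray(v) for e, v in per_event.items() if len(v) >= 2}
    skipped = tuple(e for e in TEMPLATE_EVENTS if e not in tested)
    m = len(tested)
    if m == 0:
        raise InsufficientDataError("no event windows fit inside any trial trace")
    baseline = np.asarray(base_slopes)
    p_values = {}
    for e, v in tested.items():
        with np.errstate(invalid="ignore"):
            p = float(stats.ttest_ind(v, baseline).pvalue)
        # degenerate zero-variance comparisons (e.g. identically zero traces)
        p_values[e] = 1.0 if np.isnan(p) else p
    corrected_alpha = alpha / m
    active = any(p < corrected_alpha for p in p_values.values())
    return EventSlopeTest(
        events=tuple(tested),
        p_values=p_values,
        slopes=tested,
        baseline_slopes=baseline,
        bonferroni_m=m,
        corrected_alpha=corrected_alpha,
        escape_active=active,
        skipped_events=skipped,
    )


def repair_artifact(
    trace: Sequence[float],
    frame_rate: float,
    trough_times: Sequence[float],
    half_width_s: float = 0.5,
) -> np.ndarray:
    """Replace +/-``half_width_s`` around each artifact trough by cubic
    interpolation anchored on the flanking data."""
    x = np.asarray(trace, dtype=float).copy()
    n = x.size
    half = int(round(half_width_s * frame_rate))
    remove = np.zeros(n, dtype=bool)
    for t in trough_times:
        c = int(round(t * frame_rate))
        i0, i1 = c - half, c + half + 1
        if i0 <= 0 or i1 >= n:
            raise ValueError(
                f"artifact window around t={t:.3f} s exceeds trace bounds"
            )
        remove[i0:i1] = True
    if not remove.any():
        return x
    keep = np.flatnonzero(~remove)
    spline = CubicSpline(keep, x[keep])
    gaps = np.flatnonzero(remove)
    x[gaps] = spline(gaps)
    return x


def build_template(
    trials: Sequence[Mapping[str, float]],
    grid_rate: float = TEMPLATE_GRID_RATE_HZ,
    tail: float = TEMPLATE_TAIL_S,
) -> WarpTemplate:
    """Median event-relative times over complete trials -> WarpTemplate.

    Each trial supplies absolute event times; per event the time relative to
    that trial's stimulus onset is collected and the across-trial median
    taken. Trials missing any template event are ignored; at least one
    complete trial is required.
    """
    rel: dict[str, list[float]] = {e: [] for e in TEMPLATE_EVENTS}
    n_complete = 0
    for events in trials:
        ev = _canonical(events)
        if not all(e in ev for e in TEMPLATE_EVENTS):
            continue
        n_complete += 1
        stim = ev["stimulus"]
        for e in TEMPLATE_EVENTS:
            rel[e].append(ev[e] - stim)
    if n_complete == 0:
        raise InsufficientDataError("no trial with the complete event sequence")
    times = np.array([np.median(rel[e]) for e in TEMPLATE_EVENTS])
    return WarpTemplate(
        event_names=TEMPLATE_EVENTS,
        template_times=times,
        grid_rate=grid_rate,
        tail=tail,
    )


def warp_trace(
    trace: Sequence[float],
    frame_rate: float,
    trial_events: Mapping[str, float],
    template: WarpTemplate,
) -> np.ndarray:
    """Linearly time warp one trial's trace onto the template grid.

    The piecewise-linear time map sends each trial event time to its
    template time; between anchors the map interpolates linearly, and beyond
    the first/last anchor it extends with identity slope. The warped trace
    is the input linearly interpolated at the mapped trial times; values at
    event anchors are preserved, the map is monotone by construction, and
    warping an already-template-timed trace is the identity on the grid.
    """
    x = np.asarray(trace, dtype=float)
    ev = _canonical(trial_events)
    try:
        taus = np.array([ev[e] for e in template.event_names])
    except KeyError as exc:
        raise ValueError(f"trial is missing template event {exc}") from exc
    if np.any(np.diff(taus) <= 0):
        raise ValueError("trial event times out of order")
    anchors_t = template.template_times  # template coordinates
    grid = template.grid
    # inverse map: template time -> trial time
    trial_t = np.interp(grid, anchors_t, taus)
    before = grid < anchors_t[0]
    after = grid > anchors_t[-1]
    trial_t[before] = taus[0] + (grid[before] - anchors_t[0])
    trial_t[after] = taus[-1] + (grid[after] - anchors_t[-1])
    assert np.all(np.diff(trial_t) > 0), "time map must be monotone increasing"
    sample_t = np.arange(x.size) / frame_rate
    return np.interp(trial_t, sample_t, x)


@dataclass(frozen=True)
class MeanResponse:
    mean_escape: np.ndarray | None
    mean_fail: np.ndarray | None
    window_mean_escape: float | None
    window_mean_fail: float | None
    n_escape: int
    n_fail: int


def mean_response(
    trials: Sequence[tuple[Sequence[float], Mapping[str, float], str]],
    frame_rate: float,
    template: WarpTemplate,
    window: tuple[str, str] = ("reaction", "escape_stop"),
) -> MeanResponse:
    """Per-neuron mean warped trace, separately for escape and fail trials.

    ``trials`` holds ``(baselined trace, event-time map, outcome)``. Fail
    trials carry no post-reaction events, so they are mapped with the
    identity warp anchored at stimulus onset (sampled at template times) —
    the "same period" comparison. The summary statistic is the mean z
    between the reaction (startle) and escape-stop template anchors.
    """
    escape_rows, fail_rows = [], []
    for trace, events, outcome in trials:
        ev = _canonical(events)
        if outcome == "escape":
            escape_rows.append(warp_trace(trace, frame_rate, ev, template))
        else:
            pseudo = {
                e: ev["stimulus"] + template.anchor_time(e)
                for e in template.event_names
            }
            fail_rows.append(warp_trace(trace, frame_rate, pseudo, template))
    grid = template.grid
    i0 = int(round(template.anchor_time(window[0]) * template.grid_rate))
    i1 = int(round(template.anchor_time(window[1]) * template.grid_rate)) + 1

    def agg(rows: list[np.ndarray]) -> tuple[np.ndarray | None, float | None]:
        if not rows:
            return None, None
        m = np.mean(rows, axis=0)
        return m, float(m[i0:i1].mean())

    mean_esc, win_esc = agg(escape_rows)
    mean_fail, win_fail = agg(fail_rows)
    return MeanResponse(
        mean_escape=mean_esc,
        mean_fail=mean_fail,
        window_mean_escape=win_esc,
        window_mean_fail=win_fail,
        n_escape=len(escape_rows),
        n_fail=len(fail_rows),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_event_times_csv(path: str | Path) -> dict[str, dict[str, float]]:
    """CSV (trial_id, event_name, time_s) -> {trial_id: {event: time}}."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, float]] = {}
    for tid, grp in df.groupby("trial_id", sort=True):
        out[str(tid)] = dict(zip(grp["event_name"], grp["time_s"].astype(float)))
    return out


def write_warped_h5(
    warped: np.ndarray, template: WarpTemplate, path: str | Path
) -> None:
    """(neuron x template-grid) warped means + template metadata."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("warped", data=np.asarray(warped, dtype=float))
        d.attrs["grid_rate"] = template.grid_rate
        f.create_dataset("template_times", data=template.template_times)
        f.create_dataset(
            "event_names",
            data=np.array(template.event_names, dtype=h5py.string_dtype()),
        )
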