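"""Escape-trial classification and behavioural metrics.

A successful escape is the full annotated event sequence — stimulus-reaction
(startle), shelter-directed turn, escape run, shelter entry — with an
uninterrupted run into the shelter within 6 s of stimulus end (7.5 s for
head-mounted-microscope imaging sessions). Derived metrics: per-animal
escape probability, peak escape speed from run initiation to shelter entry,
normalized termination distance (0 = shelter entrance, 1 = arena far end;
negative values mean the animal stopped past the entrance), and escape path
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EscapeTrial",
    "ArenaGeometry",
    "classify_escape",
    "escape_probability",
    "peak_escape_speed",
    "termination_distance",
    "escape_path_length",
    "read_trials_csv",
]

ESCAPE_DEADLINE_S = 6.0
IMAGING_ESCAPE_DEADLINE_S = 7.5
#: stand-in for the manual "uninterrupted run" criterion
STOP_SPEED_CMPS = 5.0
STOP_MAX_DURATION_S = 0.5

EVENT_ORDER = ("reaction", "turn", "run_start", "shelter_entry", "escape_stop")
EVENT_ALIASES = {"startle": "reaction", "run": "run_start"}


@dataclass
class EscapeTrial:
    """One threat trial: stimulus timing, annotated events, aligned tracking.

    ``events`` maps names in :data:`EVENT_ORDER` (aliases ``startle``/``run``
    accepted) to absolute session times; present events must ascend in the
    listed order. ``speed`` is cm/s, ``position`` cm (1-D along the arena
    axis or (n, 2)); both on a uniform grid at ``frame_rate``.
    """

    stimulus_onset: float
    stimulus_end: float
    events: dict[str, float]
    speed: np.ndarray | None = None
    position: np.ndarray | None = None
    frame_rate: float = 30.0
    laser_condition: Literal["off", "on", "on_only"] = "off"
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.events = {
            EVENT_ALIASES.get(k, k): float(v) for k, v in self.events.items()
        }
        ordered = [self.events[e] for e in EVENT_ORDER if e in self.events]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("present event times must ascend in canonical order")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)

    def _index(self, t: float) -> int:
        return int(round(t * self.frame_rate))


@dataclass(frozen=True)
class ArenaGeometry:
    arena_length: float  # cm
    shelter_entrance: float  # cm along the long axis
    far_end: float  # cm
    threat_zone: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = sorted((0.0, self.arena_length))
        if not (lo < self.shelter_entrance < hi) or self.far_end == self.shelter_entrance:
            raise ValueError("shelter entrance must lie strictly inside the arena")


def classify_escape(
    trial: EscapeTrial,
    deadline: float = ESCAPE_DEADLINE_S,
    imaging_deadline: float = IMAGING_ESCAPE_DEADLINE_S,
    imaging: bool = False,
    stop_speed: float = STOP_SPEED_CMPS,
    stop_max_duration: float = STOP_MAX_DURATION_S,
) -> Literal["escape", "fail"]:
    """Classify a trial as escape or fail.

    Escape requires: all of reaction, turn, run_start and shelter_entry
    annotated; shelter entry at most ``deadline`` seconds after stimulus end
    (closed bound; 7.5 s when ``imaging``); and an uninterrupted run —
    operationalised as speed during [run_start, shelter_entry] never below
    ``stop_speed`` for longer than ``stop_max_duration`` (the original
    criterion was scored manually).
    """
    required = ("reaction", "turn", "run_start", "shelter_entry")
    if any(e not in trial.events for e in required):
        return "fail"
    entry = trial.events["shelter_entry"]
    limit = imaging_deadline if imaging else deadline
    if entry - trial.stimulus_end > limit:
        return "fail"
    if trial.speed is not None:
        i0 = trial._index(trial.events["run_start"])
        i1 = trial._index(entry)
        if i1 > trial.speed.size:
            raise ValueError("speed trace does not cover the run window")
        run = trial.speed[i0:i1]
        slow = run < stop_speed
        max_slow = int(round(stop_max_duration * trial.frame_rate))
        # longest contiguous below-threshold stretch
        count = longest = 0
        for s in slow:
            count = count + 1 if s else 0
            longest = max(longest, count)
        if longest > max_slow:
            return "fail"
    return "escape"


def escape_probability(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-animal escape probability, optionally per condition.

    ``trials`` needs columns ``animal_id`` and ``outcome``
    ("escape"/"fail"), optionally ``condition``. Returns one row per
    animal (x condition) with n_trials, n_escapes and probability;
    condition-level summaries are means over animals of these fractions.
    """
    if trials.empty:
        raise ValueError("no trials provided")
    keys = ["animal_id"] + (["condition"] if "condition" in trials.columns else [])
    rows = []
    for key, grp in trials.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        k = int((grp["outcome"] == "escape").sum())
        rows.append(dict(zip(keys, key)) | {
            "n_trials": n,
            "n_escapes": k,
            "escape_probability": k / n,
        })
    return pd.DataFrame(rows)


def peak_escape_speed(
    trial: EscapeTrial, from_event: Literal["run_start", "turn"] = "run_start"
) -> float:
    """Maximum speed between escape initiation and shelter entry (cm/s)."""
    if classify_escape(trial) != "escape":
        raise ValueError("peak escape speed is defined for escape trials only")
    if trial.speed is None:
        raise ValueError("trial carries no speed trace")
    i0 = trial._index(trial.events[from_event])
    i1 = trial._index(trial.events["shelter_entry"]) + 1
    return float(np.max(trial.speed[i0:i1]))


def termination_distance(stop_position: float, geometry: ArenaGeometry) -> float:
    """Normalized distance from the shelter at which the escape run stopped.

    0 at the shelter entrance, 1 at the arena far end; stopping past the
    entrance (toward/inside the shelter) gives a negative value. Invariant to
    translating all coordinates.
    """
    span = geometry.far_end - geometry.shelter_entrance
    if span == 0:
        raise ValueError("degenerate geometry: far end equals shelter entrance")
    return (stop_position - geometry.shelter_entrance) / span


def escape_path_length(trial: EscapeTrial) -> float:
    """Summed Euclidean step length of the trajectory from run start to
    escape stop (cm). Uses the full 2-D track when available."""
    if trial.position is None:
        raise ValueError("trial carries no position track")
    end_event = "escape_stop" if "escape_stop" in trial.events else "shelter_entry"
    if "run_start" not in trial.events or end_event not in trial.events:
        raise ValueError("run_start and escape stop annotations required")
    i0 = trial._index(trial.events["run_start"])
    i1 = trial._index(trial.events[end_event]) + 1
    pos = trial.position[i0:i1]
    if pos.ndim == 1:
        steps = np.abs(np.diff(pos))
    else:
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(steps.sum())


def read_trials_csv(events_path: str | Path) -> pd.DataFrame:
    """Trial annotations from long-format CSV
    (trial_id, animal_id, event_name, time_s)."""
    df = pd.read_csv(events_path)
    wide = df.pivot_table(
        index=["trial_id", "animal_id"],
        columns="event_name",
        values="time_s",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    return wide
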