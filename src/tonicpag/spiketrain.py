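"""Firing-rate, ISI-regularity and passive-membrane metrics.

Metrics for tonically firing neurons recorded in loose-seal cell-attached or
whole-cell configuration: mean firing rate in an explicit analysis window, the
coefficient of variation of inter-spike intervals (CV), the local regularity
statistic CV2 (Holt-style: ``2|dt_{i+1} - dt_i| / (dt_{i+1} + dt_i)`` averaged
over consecutive interval pairs; 0 for a perfectly regular train, 1 for
Poisson firing), input resistance and membrane time constant from a
hyperpolarising test pulse, and f-I curves from current-step families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SpikeTrain",
    "IsiStats",
    "PassiveProperties",
    "TauFit",
    "InsufficientDataError",
    "FitError",
    "firing_rate",
    "isi_cv",
    "isi_cv2",
    "isi_stats",
    "input_resistance",
    "membrane_tau",
    "fi_curve",
    "read_spike_trains_csv",
    "write_isi_stats_csv",
]


class InsufficientDataError(ValueError):
    """Raised when a metric needs more spikes/samples than were provided."""


class FitError(RuntimeError):
    """Raised when a model fit fails to converge or is degenerate."""


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered list of spike times within a recording of known duration.

    Times are in seconds, strictly increasing, within ``[0, duration]``.
    """

    spike_times: np.ndarray
    duration: float
    unit_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class IsiStats:
    mean_rate: float  # Hz
    cv: float
    cv2: float
    n_spikes: int


@dataclass(frozen=True)
class PassiveProperties:
    input_resistance: float  # MOhm
    membrane_tau: float  # ms
    resting_potential: float  # mV


@dataclass(frozen=True)
class TauFit:
    """Single-exponential fit ``y = y0 + A * exp(-(x - x0)/tau)``."""

    tau_ms: float
    y0: float
    amplitude: float
    x0_s: float
    residual_rms: float


def firing_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Mean firing rate (Hz) over a half-open window ``[start, end)``.

    Half-open counting avoids double-counting a spike sitting exactly on a
    shared bin edge when rates over adjacent windows are combined.
    """
    start, end = window
    if not (0 <= start < end <= train.duration):
        raise ValueError(
            f"window [{start}, {end}) must be non-empty and within [0, {train.duration}]"
        )
    n = int(np.count_nonzero((train.spike_times >= start) & (train.spike_times < end)))
    return n / (end - start)


def isi_cv(train: SpikeTrain, sample_sd: bool = False) -> float:
    """Coefficient of variation of the ISIs: SD of ISIs over the mean ISI.

    Population SD by default (``sample_sd=True`` switches to the n-1
    normalisation); requires at least 3 spikes (2 intervals).
    """
    if train.n_spikes < 3:
        raise InsufficientDataError("isi_cv requires at least 3 spikes")
    isis = train.isis()
    sd = float(np.std(isis, ddof=1 if sample_sd else 0))
    return sd / float(np.mean(isis))


def isi_cv2(train: SpikeTrain) -> float:
    """Local ISI-variability statistic CV2.

    ``mean over i of 2|dt_{i+1} - dt_i| / (dt_{i+1} + dt_i)`` for consecutive
    interval pairs. Bounded in [0, 2]; 0 for perfectly regular firing, 1 in
    expectation for exponential (Poisson) ISIs. Invariant to uniform time
    rescaling.
    """
    if train.n_spikes < 3:
        raise InsufficientDataError("isi_cv2 requires at least 3 spikes (2 ISIs)")
    isis = train.isis()
    a, b = isis[:-1], isis[1:]
    return float(np.mean(2.0 * np.abs(b - a) / (b + a)))


def isi_stats(train: SpikeTrain, window: tuple[float, float] | None = None) -> IsiStats:
    """Convenience bundle of rate, CV and CV2 over an analysis window."""
    if window is None:
        window = (0.0, train.duration)
    return IsiStats(
        mean_rate=firing_rate(train, window),
        cv=isi_cv(train),
        cv2=isi_cv2(train),
        n_spikes=train.n_spikes,
    )


def input_resistance(v_baseline: float, v_steady: float, i_step: float) -> float:
    """Input resistance in MOhm from a current test pulse (Ohm's law).

    ``(v_steady - v_baseline) [mV] / i_step [pA]`` gives GOhm x 1e-3, i.e.
    mV/pA = 1000 MOhm. A passive response to a hyperpolarising step yields a
    positive value (both deflection and step negative).
    """
    if i_step == 0:
        raise ValueError("current step must be non-zero")
    return (v_steady - v_baseline) / i_step * 1000.0


def membrane_tau(
    time_s: Sequence[float],
    voltage_mv: Sequence[float],
    x0: float | None = None,
) -> TauFit:
    """Membrane time constant from a single-exponential fit to a pulse decay.

    Least-squares fit of ``y = y0 + A*exp(-(x - x0)/tau)``; ``x0`` defaults to
    the first sample. Returns tau in ms with fit diagnostics. Raises
    :class:`FitError` for degenerate (flat) segments or non-convergence.
    """
    x = np.asarray(time_s, dtype=float)
    y = np.asarray(voltage_mv, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("membrane_tau requires at least 4 samples")
    if x0 is None:
        x0 = float(x[0])
    span = float(np.ptp(y))
    if span == 0.0:
        raise FitError("flat segment: exponential amplitude is degenerate")

    def model(xx: np.ndarray, y0: float, amp: float, tau: float) -> np.ndarray:
        return y0 + amp * np.exp(-(xx - x0) / tau)

    a0 = y[0] - y[-1]
    tau0 = max((x[-1] - x[0]) / 5.0, 1e-6)
    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=(float(y[-1]), float(a0), tau0),
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy detail
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    y0_fit, amp, tau = (float(v) for v in popt)
    resid = y - model(x, y0_fit, amp, tau)
    rms = float(np.sqrt(np.mean(resid**2)))
    if abs(amp) < 1e-9 * max(1.0, abs(y0_fit)) or rms > span:
        raise FitError(f"degenerate fit (A={amp:.3g}, residual RMS={rms:.3g})")
    return TauFit(tau_ms=tau * 1000.0, y0=y0_fit, amplitude=amp, x0_s=x0, residual_rms=rms)


def fi_curve(
    step_trains: Iterable[tuple[float, SpikeTrain]],
) -> list[tuple[float, float]]:
    """f-I curve: mean firing rate per injected-current step.

    Input is ``(current_pA, SpikeTrain)`` pairs, one per repetition; each
    train's window is its full duration (the current-step length, typically
    500 ms). Repetitions at the same current are averaged; all repetitions at
    a step must share the same window length.
    """
    by_current: dict[float, list[SpikeTrain]] = {}
    for current, train in step_trains:
        by_current.setdefault(float(current), []).append(train)
    if not by_current:
        raise ValueError("no current steps provided")
    out: list[tuple[float, float]] = []
    for current in sorted(by_current):
        trains = by_current[current]
        durations = {t.duration for t in trains}
        if len(durations) > 1:
            raise ValueError(
                f"repetition windows at {current} pA differ: {sorted(durations)}"
            )
        rates = [t.n_spikes / t.duration for t in trains]
        out.append((current, float(np.mean(rates))))
    return out


# ---------------------------------------------------------------------------
# I/O: spike trains from long-format CSV (unit_id, time_s); summaries to CSV.
# ---------------------------------------------------------------------------


def read_spike_trains_csv(path: str | Path, duration: float) -> dict[str, SpikeTrain]:
    df = pd.read_csv(path)
    if not {"unit_id", "time_s"} <= set(df.columns):
        raise ValueError("spike-train CSV must have columns unit_id, time_s")
    out = {}
    for unit, grp in df.groupby("unit_id", sort=True):
        times = np.sort(grp["time_s"].to_numpy(dtype=float))
        out[str(unit)] = SpikeTrain(times, duration=duration, unit_id=str(unit))
    return out


def write_isi_stats_csv(stats: dict[str, IsiStats], path: str | Path) -> None:
    rows = [
        {
            "unit_id": unit,
            "mean_rate_hz": s.mean_rate,
            "cv": s.cv,
            "cv2": s.cv2,
            "n_spikes": s.n_spikes,
        }
        for unit, s in stats.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
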