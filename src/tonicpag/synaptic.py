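"""IPSC detection and quantification for voltage-clamp recordings.

Threshold-based detection of spontaneous inhibitory postsynaptic currents on
a rolling-median baseline, event frequency over configurable window schemes,
peak conductance (G = I / V_hold, valid with a high-chloride internal where
E_Cl ~ 0 mV so the driving force equals the holding potential), unitary
charge over a 50 ms window from event onset, paired-pulse ratio, evoked
responses (sweep averaging, latency from onset-fraction crossing), and
normalized drug effects on event frequency with the wash-in window presets
used for CNO (minutes 7-8 after onset) and SR-95531 (minutes 5-7).

Amplitudes are kept signed internally (negative-going inward currents at
negative holding potentials); summary quantities report magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spiketrain import InsufficientDataError

__all__ = [
    "CurrentRecording",
    "DetectedEvent",
    "SynapticSummary",
    "FrequencyResult",
    "EvokedResult",
    "detect_events",
    "event_frequency",
    "peak_conductance",
    "unitary_charge",
    "average_charge_rate",
    "paired_pulse_ratio",
    "evoked_response",
    "drug_effect",
    "rolling_median_baseline",
    "robust_noise_sd",
    "read_recording_csv",
    "write_events_csv",
]

#: wash-in analysis windows, minutes after drug onset
DRUG_POST_WINDOWS_MIN: dict[str, tuple[float, float]] = {
    "CNO": (7.0, 8.0),
    "SR-95531": (5.0, 7.0),
}
BASELINE_WINDOW_MIN = 2.0  # minutes before drug onset


@dataclass(frozen=True)
class CurrentRecording:
    """Sampled current trace with acquisition metadata.

    ``samples`` in pA, ``sample_rate`` in kHz, ``holding_potential`` in mV.
    ``epochs`` are non-overlapping labelled ``(label, start_s, end_s)``
    spans; ``stim_times`` are optional stimulus onsets for evoked protocols.
    """

    samples: np.ndarray
    sample_rate: float  # kHz
    holding_potential: float  # mV
    epochs: tuple[tuple[str, float, float], ...] = ()
    stim_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        spans = sorted((s, e) for _, s, e in self.epochs)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("epochs must be non-overlapping")
        for _, s, e in self.epochs:
            if not (0 <= s < e <= self.duration + 1e-9):
                raise ValueError("epochs must lie within the record")

    @property
    def fs_hz(self) -> float:
        return self.sample_rate * 1000.0

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs_hz

    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass(frozen=True)
class DetectedEvent:
    onset: float  # s
    peak_time: float  # s
    peak_amplitude: float  # pA, signed
    charge: float  # pC, magnitude


@dataclass(frozen=True)
class SynapticSummary:
    frequency: float  # Hz
    mean_peak_amplitude: float  # pA, magnitude
    peak_conductance: float  # nS
    unitary_charge: float  # pC
    average_charge_rate: float  # pC/s


def rolling_median_baseline(
    samples: np.ndarray, fs_hz: float, window_s: float = 1.0
) -> np.ndarray:
    """Rolling-median baseline, evaluated on a coarse grid and interpolated.

    Exact dense rolling medians are needless at synaptic timescales; medians
    over the full window are computed every window/20 samples and linearly
    interpolated back to the sample grid.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    win = max(3, int(round(window_s * fs_hz)))
    if win >= n:
        return np.full(n, np.median(x))
    step = max(1, win // 20)
    centers = np.arange(0, n, step)
    half = win // 2
    meds = np.array(
        [np.median(x[max(0, c - half) : min(n, c + half + 1)]) for c in centers]
    )
    return np.interp(np.arange(n), centers, meds)


def robust_noise_sd(residual: np.ndarray) -> float:
    """Noise SD estimated as 1.4826 x MAD of the baseline-subtracted trace."""
    r = np.asarray(residual, dtype=float)
    return float(1.4826 * np.median(np.abs(r - np.median(r))))


def detect_events(
    rec: CurrentRecording,
    threshold: float | None = None,
    threshold_sd: float = 4.0,
    min_interval_ms: float = 5.0,
    polarity: Literal[-1, 1] = -1,
    onset_fraction: float = 0.1,
    baseline_window_s: float = 1.0,
    charge_window_ms: float = 50.0,
    smooth_ms: float = 1.0,
) -> list[DetectedEvent]:
    """Threshold detection of synaptic events on a rolling-median baseline.

    ``threshold`` is an absolute amplitude in pA; when omitted it defaults to
    ``threshold_sd`` times the robust noise SD (MAD of the baseline-subtracted
    residual). The residual is boxcar-smoothed over ``smooth_ms`` before
    peak-finding so noise ripple on decay tails does not split events.
    Peaks in the configured polarity separated by at least
    ``min_interval_ms`` are kept; each event's onset is the last crossing of
    ``onset_fraction`` of its peak amplitude before the peak, and its charge
    is the trapezoidal integral of the residual over ``charge_window_ms``
    from onset (pA x s = pC).
    """
    fs = rec.fs_hz
    min_gap = int(round(min_interval_ms / 1000.0 * fs))
    if rec.samples.size < 2 * max(min_gap, 1):
        raise InsufficientDataError("trace shorter than twice the refractory interval")
    baseline = rolling_median_baseline(rec.samples, fs, baseline_window_s)
    resid = rec.samples - baseline
    if threshold is None:
        threshold = threshold_sd * robust_noise_sd(resid)
    if threshold <= 0:
        raise ValueError("threshold magnitude must be positive")
    smooth_n = max(1, int(round(smooth_ms / 1000.0 * fs)))
    if smooth_n > 1:
        resid = np.convolve(resid, np.ones(smooth_n) / smooth_n, mode="same")
    signal = polarity * resid  # events become positive-going
    # height alone over-counts: noise riding on a decay tail makes spurious
    # local maxima. Requiring prominence >= threshold means a peak must rise
    # by a full threshold above the minimum separating it from its
    # neighbours, which rejects tail noise yet keeps genuinely overlapping
    # events that each carry their own rise.
    wlen = max(2 * min_gap + 1, int(round(0.1 * fs)))
    peaks, _ = find_peaks(
        signal,
        height=threshold,
        prominence=threshold,
        distance=max(min_gap, 1),
        wlen=wlen,
    )
    charge_n = int(round(charge_window_ms / 1000.0 * fs))
    events: list[DetectedEvent] = []
    for p in peaks:
        amp = signal[p]
        onset_level = onset_fraction * amp
        i = p
        while i > 0 and signal[i - 1] > onset_level:
            i -= 1
        onset_idx = i
        seg = resid[onset_idx : onset_idx + charge_n + 1]
        charge = abs(float(np.trapezoid(seg, dx=1.0 / fs)))
        events.append(
            DetectedEvent(
                onset=onset_idx / fs,
                peak_time=p / fs,
                peak_amplitude=float(polarity * amp),
                charge=charge,
            )
        )
    return events


@dataclass(frozen=True)
class FrequencyResult:
    windows: tuple[tuple[float, float], ...]
    rates: tuple[float, ...]  # Hz per window
    mean: float  # Hz, whole-record mean


def event_frequency(
    event_times: Sequence[float],
    record_duration: float,
    scheme: Literal["whole", "per_minute", "continuous_30s_per_min"] = "whole",
) -> FrequencyResult:
    """Event frequency per analysis window plus the whole-record mean.

    Schemes: the whole record; per-minute bins; or a continuous 30 s window
    at the start of every minute.
    """
    t = np.asarray(event_times, dtype=float)
    if record_duration <= 0:
        raise ValueError("record_duration must be positive")
    if scheme == "whole":
        windows = [(0.0, record_duration)]
    elif scheme == "per_minute":
        edges = np.arange(0.0, record_duration + 1e-9, 60.0)
        if edges[-1] < record_duration:
            edges = np.append(edges, record_duration)
        windows = list(zip(edges[:-1], edges[1:]))
    elif scheme == "continuous_30s_per_min":
        starts = np.arange(0.0, record_duration, 60.0)
        windows = [(s, min(s + 30.0, record_duration)) for s in starts]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not windows:
        raise ValueError("empty window list")
    rates = tuple(
        float(np.count_nonzero((t >= a) & (t < b)) / (b - a)) for a, b in windows
    )
    mean = float(t.size / record_duration)
    return FrequencyResult(tuple(windows), rates, mean)


def peak_conductance(mean_peak_current: float, v_hold: float) -> float:
    """Peak conductance |I / V_hold| in nS (pA / mV = nS)."""
    if v_hold == 0:
        raise ValueError("holding potential must be non-zero")
    return abs(mean_peak_current / v_hold)


def unitary_charge(
    time_s: Sequence[float],
    current_pa: Sequence[float],
    onset: float = 0.0,
    baseline: float = 0.0,
    window_ms: float = 50.0,
) -> float:
    """Charge of a mean event waveform: |trapezoidal integral| over
    ``[onset, onset + window_ms]`` of the baseline-subtracted current, in pC.
    """
    t = np.asarray(time_s, dtype=float)
    i = np.asarray(current_pa, dtype=float) - baseline
    end = onset + window_ms / 1000.0
    if t[-1] + 1e-12 < end:
        raise ValueError(
            f"waveform spans only {t[-1] - onset:.4f} s from onset; "
            f"{window_ms / 1000.0:.4f} s required"
        )
    mask = (t >= onset) & (t <= end + 1e-12)
    return abs(float(np.trapezoid(i[mask], t[mask])))


def average_charge_rate(unitary_charge_pc: float, frequency_hz: float) -> float:
    """Average charge transfer per second: unitary charge x event frequency."""
    if unitary_charge_pc < 0 or frequency_hz < 0:
        raise ValueError("unitary charge and frequency must be non-negative")
    return unitary_charge_pc * frequency_hz


def paired_pulse_ratio(pulse_peaks: Sequence[Sequence[float]] | Sequence[float]) -> float:
    """Paired-pulse ratio: mean second-pulse peak / mean first-pulse peak.

    Accepts one ``(p1, p2, ...)`` amplitude tuple or a sequence of per-sweep
    tuples; means are taken across sweeps before the ratio.
    """
    arr = np.atleast_2d(np.asarray(pulse_peaks, dtype=float))
    if arr.shape[1] < 2:
        raise ValueError("at least two pulse amplitudes required")
    means = arr.mean(axis=0)
    if means[0] == 0:
        raise ZeroDivisionError("first-pulse mean amplitude is zero")
    return float(means[1] / means[0])


@dataclass(frozen=True)
class EvokedResult:
    mean_amplitudes: tuple[float, ...]  # pA, signed, one per pulse
    latency_ms: float | None  # onset latency of the first pulse; None if unconnected
    ppr: float | None
    connected: bool
    mean_trace: np.ndarray = field(repr=False, default=None)


def evoked_response(
    rec: CurrentRecording,
    sweep_stim_times: Sequence[Sequence[float]],
    n_min_sweeps: int = 5,
    search_window_ms: float = 20.0,
    onset_fraction: float = 0.2,
    polarity: Literal[-1, 1] = -1,
    detection_sd: float = 3.0,
    amplitude_mode: Literal["peak_of_average", "average_of_peaks"] = "peak_of_average",
) -> EvokedResult:
    """Evoked-IPSC amplitude, onset latency and paired-pulse ratio.

    ``sweep_stim_times`` lists, per sweep, the pulse times of the stimulus
    train. Sweeps are aligned on their first pulse and averaged; per-pulse
    amplitude is the extremum of the average in a post-pulse search window
    (or the across-sweep mean of per-sweep extrema with
    ``amplitude_mode="average_of_peaks"``). Latency is the time at which the
    average first crosses ``onset_fraction`` of the first-pulse peak. A cell
    is classified unconnected when the first-pulse amplitude stays below
    ``detection_sd`` pre-stimulus noise SDs.
    """
    sweeps = [np.asarray(s, dtype=float) for s in sweep_stim_times]
    if len(sweeps) < n_min_sweeps:
        raise InsufficientDataError(
            f"{len(sweeps)} sweeps provided, minimum is {n_min_sweeps}"
        )
    n_pulses = {s.size for s in sweeps}
    if len(n_pulses) != 1:
        raise ValueError("all sweeps must have the same number of pulses")
    n_pulses = n_pulses.pop()
    fs = rec.fs_hz
    rel_pulses = sweeps[0] - sweeps[0][0]
    pre_n = int(round(0.005 * fs))
    search_n = int(round(search_window_ms / 1000.0 * fs))
    total_n = int(round(rel_pulses[-1] * fs)) + search_n

    aligned = []
    for s in sweeps:
        i0 = int(round(s[0] * fs))
        seg = rec.samples[max(0, i0 - pre_n) : i0 + total_n]
        n_pre_avail = min(pre_n, i0)
        base = np.mean(seg[:n_pre_avail]) if n_pre_avail else 0.0
        aligned.append(seg[n_pre_avail:][:total_n] - base)
    n_keep = min(len(a) for a in aligned)
    stack = np.vstack([a[:n_keep] for a in aligned])
    mean_trace = stack.mean(axis=0)

    noise_sd = robust_noise_sd(
        rec.samples[: int(round(sweeps[0][0] * fs))] if sweeps[0][0] > 0 else mean_trace
    )
    amps: list[float] = []
    first_peak_idx = None
    for k, rp in enumerate(rel_pulses):
        a = int(round(rp * fs))
        b = min(a + search_n, n_keep)
        window = polarity * mean_trace[a:b]
        idx = int(np.argmax(window))
        if amplitude_mode == "peak_of_average":
            amps.append(float(polarity * window[idx]))
        else:
            per_sweep = [float(np.max(polarity * row[a:b])) for row in stack]
            amps.append(float(polarity * np.mean(per_sweep)))
        if k == 0:
            first_peak_idx = a + idx
    connected = abs(amps[0]) > detection_sd * max(noise_sd, 1e-12)
    latency_ms = None
    if connected:
        a = int(round(rel_pulses[0] * fs))
        level = onset_fraction * abs(amps[0])
        sig = polarity * mean_trace
        i = first_peak_idx
        while i > a and sig[i - 1] > level:
            i -= 1
        latency_ms = (i - a) / fs * 1000.0
    ppr = None
    if n_pulses >= 2 and amps[0] != 0:
        ppr = amps[1] / amps[0]
    return EvokedResult(
        mean_amplitudes=tuple(amps),
        latency_ms=latency_ms,
        ppr=ppr,
        connected=connected,
        mean_trace=mean_trace,
    )


def drug_effect(
    event_times: Sequence[float],
    drug_onset: float,
    post_window_min: tuple[float, float] | None = None,
    preset: str | None = None,
    baseline_window_min: float = BASELINE_WINDOW_MIN,
) -> float:
    """Normalized drug effect on event frequency.

    Baseline frequency from the ``baseline_window_min`` minutes before drug
    onset; post frequency from ``post_window_min`` (minutes after onset), or
    the preset wash-in window (``"CNO"``: min 7-8; ``"SR-95531"``: min 5-7).
    Returns post/baseline.
    """
    if post_window_min is None:
        if preset is None:
            raise ValueError("provide post_window_min or a drug preset")
        post_window_min = DRUG_POST_WINDOWS_MIN[preset]
    t = np.asarray(event_times, dtype=float)
    b0 = drug_onset - baseline_window_min * 60.0
    if b0 < -1e-9:
        raise ValueError("record does not cover the baseline window")
    base_rate = np.count_nonzero((t >= b0) & (t < drug_onset)) / (
        baseline_window_min * 60.0
    )
    if base_rate == 0:
        raise ZeroDivisionError("baseline frequency is zero; effect undefined")
    p0 = drug_onset + post_window_min[0] * 60.0
    p1 = drug_onset + post_window_min[1] * 60.0
    post_rate = np.count_nonzero((t >= p0) & (t < p1)) / (p1 - p0)
    return float(post_rate / base_rate)


def summarize(
    events: Sequence[DetectedEvent], rec: CurrentRecording
) -> SynapticSummary:
    """Per-cell summary of detected spontaneous events."""
    freq = len(events) / rec.duration
    if events:
        amps = np.array([e.peak_amplitude for e in events])
        charges = np.array([e.charge for e in events])
        mean_amp = float(np.mean(np.abs(amps)))
        mean_charge = float(np.mean(charges))
        cond = peak_conductance(float(np.mean(amps)), rec.holding_potential)
    else:
        mean_amp = mean_charge = cond = 0.0
    return SynapticSummary(
        frequency=freq,
        mean_peak_amplitude=mean_amp,
        peak_conductance=cond,
        unitary_charge=mean_charge,
        average_charge_rate=average_charge_rate(mean_charge, freq),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_recording_csv(
    path: str | Path, holding_potential: float = -70.0
) -> CurrentRecording:
    """Two-column CSV (time_s, current_pa) -> CurrentRecording."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    fs_khz = 1.0 / np.median(np.diff(t)) / 1000.0
    return CurrentRecording(
        samples=df.iloc[:, 1].to_numpy(dtype=float),
        sample_rate=fs_khz,
        holding_potential=holding_potential,
    )


def write_events_csv(events: Sequence[DetectedEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": e.onset,
                "peak_time_s": e.peak_time,
                "peak_amplitude_pa": e.peak_amplitude,
                "charge_pc": e.charge,
            }
            for e in events
        ]
    ).to_csv(path, index=False)
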