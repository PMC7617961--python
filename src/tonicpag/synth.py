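"""Seeded synthetic data with ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes, so
the whole pipeline is testable without raw recordings:

* spike trains — regular, Poisson or gamma-renewal tonic firing (the
  GABAergic dPAG phenotype is regular firing at a few Hz);
* IPSC traces — Poisson event trains with difference-of-exponentials
  kinetics, Gaussian amplitude scatter, baseline noise and drug epochs that
  rescale the event rate, with the ground-truth event list returned;
* imaging sessions — per-neuron fluorescence built by convolving a motif
  drive (ramp-to-termination, transient dip at escape onset, or
  unmodulated) with a slow-indicator kernel, plus escape trials with jittered
  event sequences, fail trials, piecewise-trapezoid speed/position traces
  and pixel masks in a stated FOV;
* movies — static illumination gradient + per-mask time-varying intensity +
  noise, for the flatfield/extraction operations.

Every generator takes an explicit seed and uses one local random generator;
identical seed and spec give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .locomotion import LocomotionBins
from .spiketrain import SpikeTrain
from .synaptic import CurrentRecording

__all__ = [
    "SpikeTrainSpec",
    "IpscTraceSpec",
    "SessionSpec",
    "SyntheticSession",
    "SyntheticTrial",
    "gen_spike_train",
    "gen_ipsc_trace",
    "gen_session",
    "gen_movie",
    "gen_lmi_bins",
    "ipsc_kernel",
    "indicator_kernel",
    "write_session_manifest",
]


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrainSpec:
    """Tonic-firing spike-train fixture.

    ``regular`` gives an exact grid (ISI = 1/rate); ``poisson`` exponential
    ISIs; ``gamma`` gamma-renewal ISIs with the given shape (shape 1 is
    Poisson; larger shapes are more regular, like the tonic phenotype).
    """

    mode: Literal["regular", "poisson", "gamma"]
    rate: float  # Hz
    duration: float  # s
    gamma_shape: float | None = None
    seed: int = 0


def gen_spike_train(spec: SpikeTrainSpec) -> SpikeTrain:
    if spec.rate <= 0 or spec.duration <= 0:
        raise ValueError("rate and duration must be positive")
    if spec.mode == "regular":
        isi = 1.0 / spec.rate
        n = int(np.floor(spec.duration * spec.rate + 1e-9))
        times = isi * np.arange(1, n + 1)
        times = np.minimum(times, spec.duration)
    else:
        rng = np.random.default_rng(spec.seed)
        # draw in blocks until the cumulative time passes the duration
        if spec.mode == "poisson":
            draw = lambda n: rng.exponential(1.0 / spec.rate, n)
        elif spec.mode == "gamma":
            if spec.gamma_shape is None or spec.gamma_shape <= 0:
                raise ValueError("gamma mode requires a positive gamma_shape")
            shape = spec.gamma_shape
            draw = lambda n: rng.gamma(shape, 1.0 / (spec.rate * shape), n)
        else:
            raise ValueError(f"unknown mode {spec.mode!r}")
        isis = []
        total = 0.0
        block = max(16, int(spec.rate * spec.duration * 1.2))
        while total <= spec.duration:
            chunk = draw(block)
            isis.append(chunk)
            total += chunk.sum()
        times = np.cumsum(np.concatenate(isis))
        times = times[times <= spec.duration]
    return SpikeTrain(times, duration=spec.duration, unit_id=f"{spec.mode}:{spec.seed}")


# ---------------------------------------------------------------------------
# IPSC traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IpscTraceSpec:
    """Spontaneous-IPSC trace fixture (negative-going events).

    Defaults give the tonic-inhibition regime: ~6.5 Hz events of roughly
    -45 pA with sub-millisecond rise and ~8 ms decay at a -70 mV holding
    potential. ``drug_epochs`` rescale the event rate within a time span,
    emulating bath wash-in.
    """

    event_rate: float = 6.5  # Hz
    amp_mean: float = -45.0  # pA
    amp_sd: float = 12.0  # pA
    rise_tau: float = 0.8  # ms
    decay_tau: float = 8.0  # ms
    noise_sd: float = 3.0  # pA
    sample_rate: float = 10.0  # kHz
    duration: float = 60.0  # s
    drug_epochs: tuple[tuple[float, float, float], ...] = ()  # (start, end, multiplier)
    holding_potential: float = -70.0  # mV
    seed: int = 0


def ipsc_kernel(rise_tau_ms: float, decay_tau_ms: float, fs_hz: float) -> np.ndarray:
    """Difference-of-exponentials kinetics, normalised to unit peak."""
    if not 0 < rise_tau_ms < decay_tau_ms:
        raise ValueError("need decay_tau > rise_tau > 0")
    t = np.arange(0, 8 * decay_tau_ms / 1000.0, 1.0 / fs_hz)
    k = np.exp(-t / (decay_tau_ms / 1000.0)) - np.exp(-t / (rise_tau_ms / 1000.0))
    return k / k.max()


def _rate_multiplier(t: float, epochs: Sequence[tuple[float, float, float]]) -> float:
    for start, end, mult in epochs:
        if start <= t < end:
            return mult
    return 1.0


def gen_ipsc_trace(spec: IpscTraceSpec) -> tuple[CurrentRecording, pd.DataFrame]:
    """Returns the recording and the ground-truth event table
    (onset_s, peak_time_s, amplitude_pa)."""
    if spec.event_rate < 0:
        raise ValueError("event_rate must be non-negative")
    if not 0 < spec.rise_tau < spec.decay_tau:
        raise ValueError("need decay_tau > rise_tau > 0")
    if spec.event_rate > 0 and 1.0 / spec.event_rate < spec.rise_tau / 1000.0:
        warnings.warn("mean inter-event interval below rise_tau: overlap regime")
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate * 1000.0
    n = int(round(spec.duration * fs))
    trace = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)

    # thinning: draw candidates at the maximum rate, keep per local multiplier
    mults = [m for _, _, m in spec.drug_epochs] + [1.0]
    max_rate = spec.event_rate * max(mults)
    onsets: list[float] = []
    if max_rate > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / max_rate)
            if t >= spec.duration:
                break
            local = spec.event_rate * _rate_multiplier(t, spec.drug_epochs)
            if rng.uniform() < local / max_rate:
                onsets.append(t)
    kernel = ipsc_kernel(spec.rise_tau, spec.decay_tau, fs)
    rise_s, decay_s = spec.rise_tau / 1000.0, spec.decay_tau / 1000.0
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    amps = rng.normal(spec.amp_mean, spec.amp_sd, len(onsets))
    amps = -np.abs(amps)  # enforce negative-going deflections
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * fs))
        seg = kernel[: n - i0]
        trace[i0 : i0 + seg.size] += amp * seg
    events = pd.DataFrame(
        {
            "onset_s": onsets,
            "peak_time_s": np.asarray(onsets) + t_peak,
            "amplitude_pa": amps,
        }
    )
    epochs = tuple(
        (f"x{m:g}", s, e) for s, e, m in spec.drug_epochs
    )
    rec = CurrentRecording(
        samples=trace,
        sample_rate=spec.sample_rate,
        holding_potential=spec.holding_potential,
        epochs=epochs,
    )
    return rec, events


# ---------------------------------------------------------------------------
# Imaging sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionSpec:
    """Synthetic freely-moving imaging session.

    Motif counts set the ground-truth composition; inter-event means/jitters
    (s) define the escape sequence relative to the previous event. The
    indicator kernel defaults to a GCaMP6s-like 0.2 s rise / 1.8 s decay.
    Drive amplitudes are set so the post-kernel responses land at
    paper-scale z excursions (~+1.3 peak for ramps, ~-0.9 trough for dips).
    """

    n_ramp: int = 12
    n_dip: int = 8
    n_unmod: int = 14
    n_trials: int = 8
    n_fail_trials: int = 3
    stimulus_duration: float = 1.0
    inter_event: tuple[tuple[str, float, float], ...] = (
        ("reaction", 0.35, 0.08),
        ("turn", 0.25, 0.08),
        ("run", 0.30, 0.10),
        ("shelter_entry", 1.20, 0.30),
        ("escape_stop", 0.30, 0.08),
    )
    kernel_rise: float = 0.2  # s
    kernel_decay: float = 1.8  # s
    ramp_amp: float = 3.0  # drive units (z after kernel attenuation ~1.3)
    dip_amp: float = 6.0  # drive units (z trough ~ -0.9)
    noise_sd: float = 0.5  # Z
    frame_rate: float = 15.0  # Hz
    baseline_duration: float = 180.0  # s before the first stimulus
    inter_trial_interval: float = 30.0  # s
    bout_speed: float = 8.0  # cm/s during locomotion bouts
    bout_duration: float = 5.0  # s
    bout_gap: float = 8.0  # s stationary between bouts
    arena_length: float = 60.0  # cm
    shelter_position: float = 10.0  # cm (entrance)
    threat_position: float = 52.0  # cm
    fov_shape: tuple[int, int] = (126, 126)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ramp + self.n_dip + self.n_unmod < 1:
            raise ValueError("at least one neuron required")
        if self.n_trials < 1:
            raise ValueError("at least one trial required")
        if not 0 < self.shelter_position < self.threat_position < self.arena_length:
            raise ValueError("shelter/threat geometry overlaps or is out of bounds")


@dataclass(frozen=True)
class SyntheticTrial:
    stimulus_onset: float
    stimulus_end: float
    events: dict[str, float]  # absolute session times
    outcome: Literal["escape", "fail"]


@dataclass(frozen=True)
class SyntheticSession:
    traces: np.ndarray  # (n_neurons, n_frames), z units
    frame_rate: float
    motifs: tuple[str, ...]  # ground-truth label per neuron
    trials: tuple[SyntheticTrial, ...]
    speed: np.ndarray  # cm/s on the frame grid
    position: np.ndarray  # cm along the arena axis
    in_shelter: np.ndarray
    masks: tuple[np.ndarray, ...]  # per-neuron (n_px, 2) pixel coordinates
    centroids: np.ndarray  # (n_neurons, 2)
    spec: SessionSpec

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.frame_rate


def indicator_kernel(rise_s: float, decay_s: float, fs_hz: float) -> np.ndarray:
    """Slow-indicator impulse response, difference of exponentials
    normalised to unit area (a sustained unit drive converges to 1)."""
    if not 0 < rise_s < decay_s:
        raise ValueError("need decay > rise > 0")
    t = np.arange(0, 6 * decay_s, 1.0 / fs_hz)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / (k.sum() / fs_hz)


def _draw_events(spec: SessionSpec, rng: np.random.Generator, onset: float) -> dict[str, float]:
    events = {"stimulus": onset}
    t = onset
    for name, mean, jitter in spec.inter_event:
        dt = max(0.05, rng.normal(mean, jitter))
        t += dt
        events[name] = t
    return events


def _place_masks(
    n: int, fov: tuple[int, int], rng: np.random.Generator
) -> tuple[list[np.ndarray], np.ndarray]:
    """Non-overlapping 3x3 pixel masks at random FOV positions."""
    h, w = fov
    taken: set[tuple[int, int]] = set()
    masks, cents = [], []
    while len(masks) < n:
        r = int(rng.integers(2, h - 2))
        c = int(rng.integers(2, w - 2))
        cell = {(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)}
        if cell & taken:
            continue
        taken |= cell
        masks.append(np.array(sorted(cell)))
        cents.append((r, c))
    return masks, np.asarray(cents, dtype=float)


def gen_session(spec: SessionSpec) -> SyntheticSession:
    rng = np.random.default_rng(spec.seed)
    fs = spec.frame_rate
    n_total_trials = spec.n_trials + spec.n_fail_trials

    # --- trial schedule -------------------------------------------------
    trials: list[SyntheticTrial] = []
    outcomes = ["escape"] * spec.n_trials + ["fail"] * spec.n_fail_trials
    rng.shuffle(outcomes)
    t = spec.baseline_duration
    for outcome in outcomes:
        onset = t + rng.uniform(0, 2.0)
        events = _draw_events(spec, rng, onset)
        if outcome == "fail":
            events = {k: events[k] for k in ("stimulus", "reaction")}
        trials.append(
            SyntheticTrial(
                stimulus_onset=onset,
                stimulus_end=onset + spec.stimulus_duration,
                events=events,
                outcome=outcome,
            )
        )
        t = onset + spec.inter_trial_interval
    duration = t + 10.0
    n_frames = int(round(duration * fs))
    time = np.arange(n_frames) / fs

    # --- behaviour: speed and 1-D position ------------------------------
    speed = np.zeros(n_frames)
    position = np.full(n_frames, spec.threat_position)
    # baseline locomotion bouts shuttling between shelter front and far end
    t_cursor, pos, direction = 2.0, spec.threat_position, -1.0
    while t_cursor + spec.bout_duration < spec.baseline_duration - 2.0:
        b0 = t_cursor + max(1.0, rng.normal(spec.bout_gap, 1.0))
        b1 = b0 + max(1.0, rng.normal(spec.bout_duration, 0.5))
        if b1 >= spec.baseline_duration - 2.0:
            break
        i0, i1 = int(b0 * fs), int(b1 * fs)
        ramp_n = max(1, int(0.5 * fs))
        prof = np.full(i1 - i0, spec.bout_speed)
        prof[:ramp_n] = np.linspace(0, spec.bout_speed, ramp_n)
        prof[-ramp_n:] = np.linspace(spec.bout_speed, 0, ramp_n)
        speed[i0:i1] = prof
        # move, reflecting off the arena limits (never enter the shelter)
        lo, hi = spec.shelter_position + 2.0, spec.arena_length - 2.0
        for i in range(i0, i1):
            pos += direction * speed[i] / fs
            if pos <= lo or pos >= hi:
                direction *= -1
                pos = float(np.clip(pos, lo, hi))
            position[i] = pos
        position[i1:] = pos
        t_cursor = b1
    # park the animal in the threat zone before the first stimulus
    i_park = int((spec.baseline_duration - 1.0) * fs)
    position[i_park:] = spec.threat_position

    for tr in trials:
        if tr.outcome != "escape":
            continue
        run0, entry = tr.events["run"], tr.events["shelter_entry"]
        stop = tr.events["escape_stop"]
        i0, i1, i2 = (int(round(x * fs)) for x in (run0, entry, stop))
        run_d = spec.threat_position - spec.shelter_position
        run_t = entry - run0
        peak_v = 2.0 * run_d / run_t  # triangular profile covering the run
        k = np.arange(i1 - i0)
        prof = peak_v * (1 - np.abs(2 * k / max(1, i1 - i0 - 1) - 1))
        speed[i0:i1] = prof
        position[i0:i1] = spec.threat_position - np.cumsum(prof) / fs
        # inside the shelter: decelerate to the stop point
        n_in = max(1, i2 - i1)
        v_in = np.linspace(prof[-1] if prof.size else 10.0, 0.0, n_in)
        speed[i1:i2] = v_in
        inward = np.cumsum(v_in) / fs
        position[i1:i2] = spec.shelter_position - inward
        stop_pos = spec.shelter_position - (inward[-1] if n_in else 0.0)
        # shelter dwell, then walk back to the threat zone
        i_exit = min(n_frames, i2 + int(5.0 * fs))
        position[i2:i_exit] = stop_pos
        speed[i2:i_exit] = 0.0
        i_back = min(n_frames, i_exit + int(6.0 * fs))
        if i_back > i_exit:
            back = np.linspace(stop_pos, spec.threat_position, i_back - i_exit)
            position[i_exit:i_back] = back
            speed[i_exit:i_back] = np.abs(np.gradient(back)) * fs
            position[i_back:] = spec.threat_position
    in_shelter = position < spec.shelter_position

    # --- neural traces ---------------------------------------------------
    motifs = ("ramp",) * spec.n_ramp + ("dip",) * spec.n_dip + (
        "unmodulated",
    ) * spec.n_unmod
    kernel = indicator_kernel(spec.kernel_rise, spec.kernel_decay, fs)
    drive = np.zeros((len(motifs), n_frames))
    for tr in trials:
        if tr.outcome != "escape":
            continue
        stim, stop = tr.events["stimulus"], tr.events["escape_stop"]
        reaction, run0 = tr.events["reaction"], tr.events["run"]
        i_stim, i_stop = int(round(stim * fs)), int(round(stop * fs))
        ramp_prof = np.linspace(0.0, 1.0, max(2, i_stop - i_stim))
        dip0 = reaction
        dip1 = reaction + 0.6 * (run0 - reaction)
        j0, j1 = int(round(dip0 * fs)), max(int(round(dip0 * fs)) + 1, int(round(dip1 * fs)))
        for n_idx, motif in enumerate(motifs):
            if motif == "ramp":
                drive[n_idx, i_stim:i_stop] = spec.ramp_amp * ramp_prof
            elif motif == "dip":
                drive[n_idx, j0:j1] = -spec.dip_amp
    traces = np.empty_like(drive)
    for n_idx in range(len(motifs)):
        conv = np.convolve(drive[n_idx], kernel / fs)[:n_frames]
        noise = rng.normal(0.0, spec.noise_sd, n_frames) if spec.noise_sd > 0 else 0.0
        traces[n_idx] = conv + noise

    masks, centroids = _place_masks(len(motifs), spec.fov_shape, rng)
    return SyntheticSession(
        traces=traces,
        frame_rate=fs,
        motifs=motifs,
        trials=tuple(trials),
        speed=speed,
        position=position,
        in_shelter=in_shelter,
        masks=tuple(masks),
        centroids=centroids,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Movies
# ---------------------------------------------------------------------------


def gen_movie(
    fov_shape: tuple[int, int],
    gradient_amplitude: float,
    masks: Sequence[np.ndarray],
    trace_amplitudes: Sequence[Sequence[float]],
    noise_sd: float = 0.0,
    frame_rate: float = 15.0,
    baseline: float = 100.0,
    seed: int = 0,
):
    """Small synthetic movie: static linear illumination gradient +
    per-mask time-varying intensity + Gaussian noise."""
    from .calcium import Movie  # local import to avoid a cycle at import time

    h, w = fov_shape
    amps = [np.asarray(a, dtype=float) for a in trace_amplitudes]
    if len(amps) != len(masks):
        raise ValueError("one amplitude trace per mask required")
    lengths = {a.size for a in amps} or {0}
    if len(lengths) != 1:
        raise ValueError("all amplitude traces must share a length")
    n_frames = lengths.pop() or 2
    for m in masks:
        m = np.asarray(m, dtype=int)
        if m.size and (m.min() < 0 or m[:, 0].max() >= h or m[:, 1].max() >= w):
            raise ValueError("mask pixels outside frame bounds")
    cols = np.linspace(0.0, gradient_amplitude, w)
    gradient = np.tile(cols, (h, 1))
    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, h, w), baseline) + gradient[None, :, :]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)
    for m, a in zip(masks, amps):
        m = np.asarray(m, dtype=int)
        frames[:, m[:, 0], m[:, 1]] += a[:, None]
    return Movie(frames, frame_rate)


# ---------------------------------------------------------------------------
# Locomotion-bin fixtures for the LMI bootstrap
# ---------------------------------------------------------------------------


def gen_lmi_bins(
    n_locomotion: int,
    n_stationary: int,
    r_locomotion: float,
    r_stationary: float,
    noise_sd: float = 0.05,
    ar1_rho: float = 0.0,
    seed: int = 0,
) -> LocomotionBins:
    """1 s state bins with known mean dF/F0 per state.

    ``ar1_rho`` adds AR(1) correlation between consecutive bins to emulate
    the non-independence the reduced-sample bootstrap compensates for.
    """
    rng = np.random.default_rng(seed)
    states = np.array(
        ["locomotion"] * n_locomotion + ["stationary"] * n_stationary
    )
    rng.shuffle(states)
    means = np.where(states == "locomotion", r_locomotion, r_stationary)
    n = states.size
    eps = rng.normal(0.0, noise_sd, n)
    if ar1_rho:
        for i in range(1, n):
            eps[i] = ar1_rho * eps[i - 1] + np.sqrt(1 - ar1_rho**2) * eps[i]
    values = (means + eps)[:, None]
    table = pd.DataFrame(
        {
            "start_s": np.arange(n, dtype=float),
            "end_s": np.arange(1, n + 1, dtype=float),
            "state": states,
        }
    )
    return LocomotionBins(table=table, values=values)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_session_manifest(spec: SessionSpec, path: str | Path) -> None:
    """Echo the generating spec as a structured text config."""
    d = asdict(spec)
    d["inter_event"] = [list(x) for x in spec.inter_event]
    d["fov_shape"] = list(spec.fov_shape)
    Path(path).write_text(yaml.safe_dump({"session_spec": d}, sort_keys=False))
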