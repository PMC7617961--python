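"""Fluorescence preprocessing for miniscope calcium imaging.

Starts from motion-corrected movies or already-extracted traces and covers:
flatfield correction (zero-centred blurred time-mean subtracted from every
frame), mask-based trace extraction with rolling-ball background subtraction,
linear resampling to the behaviour-camera rate (30 Hz), dF/F and z-scoring,
the session activity criterion (any z > 1.96), Savitzky-Golay-smoothed
transient detection (prominence 0.3 Z), and a hard-cutoff FFT low-pass.

The canonical preprocessing order is flatfield -> extraction -> resample ->
dF/F / z-score; helpers are composable but that order is what downstream
modules assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, grey_opening
from scipy.signal import find_peaks, savgol_filter
from skimage.morphology import disk

from .spiketrain import InsufficientDataError

__all__ = [
    "Movie",
    "NeuronTrace",
    "flatfield_correct",
    "block_downsample",
    "extract_trace",
    "resample_trace",
    "dff",
    "zscore",
    "dff_zscore",
    "is_active",
    "detect_transients",
    "lowpass_fft",
    "read_movie_h5",
    "write_movie_h5",
    "read_masks_csv",
    "write_traces_csv",
]

ACTIVE_Z_THRESHOLD = 1.96
BEHAVIOUR_RATE_HZ = 30.0


@dataclass(frozen=True)
class Movie:
    """A (time, row, col) intensity stack with a frame rate in Hz."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class NeuronTrace:
    """One neuron's fluorescence with its pixel mask and derived series."""

    raw: np.ndarray
    frame_rate: float
    mask: np.ndarray | None = None  # (n_pixels, 2) row/col
    neuron_id: str = ""
    dff: np.ndarray | None = field(default=None, repr=False)
    zscore: np.ndarray | None = field(default=None, repr=False)


def flatfield_correct(movie: Movie, blur_sigma: float | None = None) -> Movie:
    """Remove slowly varying illumination structure from every frame.

    The time-mean image is Gaussian-blurred (sigma defaults to 1/8 of the
    frame width), centred on zero by subtracting its own mean, and the
    zero-centred field is subtracted from all frames — so the overall movie
    mean is unchanged.
    """
    if movie.n_frames < 2:
        raise InsufficientDataError("flatfield correction needs at least 2 frames")
    if blur_sigma is None:
        blur_sigma = movie.shape[1] / 8.0
    mean_img = movie.frames.mean(axis=0)
    # nearest-edge extension keeps linear illumination trends usable at the
    # frame border, where reflect/mirror modes flatten the blurred field
    field_img = gaussian_filter(mean_img, sigma=blur_sigma, mode="nearest")
    field_img = field_img - field_img.mean()
    return Movie(movie.frames - field_img[None, :, :], movie.frame_rate)


def block_downsample(movie: Movie, factor: int = 5) -> Movie:
    """Spatial block-mean downsampling (e.g. 630x630 -> 126x126 at factor 5)."""
    t, h, w = movie.frames.shape
    if h % factor or w % factor:
        raise ValueError(f"frame shape {h}x{w} not divisible by {factor}")
    blocks = movie.frames.reshape(t, h // factor, factor, w // factor, factor)
    return Movie(blocks.mean(axis=(2, 4)), movie.frame_rate)


def extract_trace(
    movie: Movie,
    mask: np.ndarray | Sequence[tuple[int, int]],
    rollball_radius: int = 10,
) -> np.ndarray:
    """Mask-mean fluorescence after rolling-ball background subtraction.

    The per-frame background is a grayscale rolling ball — morphological
    opening with a disk structuring element of the given radius — which
    removes structures smaller than the ball (the cells) and is subtracted
    before averaging over the mask pixels.
    """
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("mask is empty")
    rows, cols = mask[:, 0], mask[:, 1]
    h, w = movie.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
        raise ValueError("mask pixels outside frame bounds")
    footprint = disk(rollball_radius)
    trace = np.empty(movie.n_frames)
    for i, frame in enumerate(movie.frames):
        background = grey_opening(frame, footprint=footprint)
        trace[i] = (frame - background)[rows, cols].mean()
    return trace


def resample_trace(
    values: Sequence[float],
    original_rate: float,
    target_rate: float = BEHAVIOUR_RATE_HZ,
) -> np.ndarray:
    """Linear interpolation onto a uniform grid at ``target_rate`` spanning
    the original support (t = 0 .. (n-1)/original_rate)."""
    x = np.asarray(values, dtype=float)
    if original_rate <= 0:
        raise ValueError("original_rate must be positive")
    if x.size < 2:
        raise InsufficientDataError("resampling needs at least 2 samples")
    t_old = np.arange(x.size) / original_rate
    t_new = np.arange(0.0, t_old[-1] + 0.5 / target_rate, 1.0 / target_rate)
    t_new = t_new[t_new <= t_old[-1] + 1e-12]
    return np.interp(t_new, t_old, x)


BaselineMethod = Literal["percentile10", "pre_window"] | Callable[[np.ndarray], float]


def _f0(values: np.ndarray, method: BaselineMethod, pre_n: int | None) -> float:
    if callable(method):
        return float(method(values))
    if method == "percentile10":
        return float(np.percentile(values, 10))
    if method == "pre_window":
        if not pre_n:
            raise ValueError("pre_window baseline requires pre_n samples")
        return float(values[:pre_n].mean())
    raise ValueError(f"unknown baseline method {method!r}")


def dff(
    values: Sequence[float],
    baseline_method: BaselineMethod = "percentile10",
    pre_n: int | None = None,
) -> np.ndarray:
    """dF/F = (F - F0)/F0. F0 defaults to the 10th percentile of the trace."""
    x = np.asarray(values, dtype=float)
    f0 = _f0(x, baseline_method, pre_n)
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:.4g} must be positive for dF/F")
    return (x - f0) / f0


def zscore(
    values: Sequence[float], window: tuple[int, int] | None = None
) -> np.ndarray:
    """Z-score over a normalisation window (default: the whole trace)."""
    x = np.asarray(values, dtype=float)
    seg = x if window is None else x[window[0] : window[1]]
    sd = float(np.std(seg))
    if sd == 0:
        raise ValueError("zero variance in normalisation window")
    return (x - float(np.mean(seg))) / sd


def dff_zscore(
    values: Sequence[float],
    baseline_method: BaselineMethod = "percentile10",
    pre_n: int | None = None,
    z_window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    d = dff(values, baseline_method, pre_n)
    return d, zscore(values, z_window)


def is_active(ztrace: Sequence[float], threshold: float = ACTIVE_Z_THRESHOLD) -> bool:
    """Session activity criterion: any z-score strictly above 1.96."""
    return bool(np.max(np.asarray(ztrace, dtype=float)) > threshold)


def detect_transients(
    ztrace: Sequence[float],
    frame_rate: float,
    window_s: float = 2.0,
    polyorder: int = 2,
    prominence: float = 0.3,
) -> tuple[np.ndarray, float]:
    """Calcium-transient times and rate from a z-scored trace.

    The trace is Savitzky-Golay smoothed (window ~2 s rounded to an odd
    sample count, order 2, reflect padding) and local maxima with prominence
    >= 0.3 Z are counted; rate = count / trace duration.
    """
    x = np.asarray(ztrace, dtype=float)
    win = int(round(window_s * frame_rate))
    win += 1 - win % 2  # odd
    if win > x.size:
        raise InsufficientDataError(
            f"smoothing window ({win} samples) longer than trace ({x.size})"
        )
    if win <= polyorder:
        raise ValueError("smoothing window must exceed the polynomial order")
    smooth = savgol_filter(x, win, polyorder, mode="mirror")
    peaks, _ = find_peaks(smooth, prominence=prominence)
    duration = x.size / frame_rate
    return peaks / frame_rate, peaks.size / duration


def lowpass_fft(
    values: Sequence[float], sample_rate: float, cutoff_hz: float = 2.0
) -> np.ndarray:
    """Hard spectral low-pass: frequency components above the cutoff zeroed.

    The identical filter is meant to be applied to every trace of a session
    so traces acquired at mixed rates stay comparable after resampling.
    """
    x = np.asarray(values, dtype=float)
    nyquist = sample_rate / 2.0
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    spectrum[freqs > cutoff_hz] = 0.0
    return np.fft.irfft(spectrum, n=x.size)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_movie_h5(movie: Movie, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("frames", data=movie.frames)
        dset.attrs["frame_rate"] = movie.frame_rate


def read_movie_h5(path: str | Path) -> Movie:
    with h5py.File(path, "r") as f:
        return Movie(f["frames"][...], float(f["frames"].attrs["frame_rate"]))


def read_masks_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Masks as CSV rows (neuron_id, row, col) -> {id: (n, 2) pixel array}."""
    df = pd.read_csv(path)
    return {
        str(nid): grp[["row", "col"]].to_numpy(dtype=int)
        for nid, grp in df.groupby("neuron_id", sort=True)
    }


def write_traces_csv(
    traces: dict[str, Sequence[float]], frame_rate: float, path: str | Path
) -> None:
    """Wide table, time_s column plus one column per neuron."""
    lengths = {len(v) for v in traces.values()}
    if len(lengths) != 1:
        raise ValueError("all traces must have equal length")
    n = lengths.pop()
    df = pd.DataFrame({"time_s": np.arange(n) / frame_rate})
    for nid, v in traces.items():
        df[nid] = np.asarray(v, dtype=float)
    df.to_csv(path, index=False)
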