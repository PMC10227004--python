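"""Movie conditioning and beat segmentation.

Raw optical recordings arrive with voltage-sensitive-dye polarity
(fluorescence falls on depolarization), arbitrary per-pixel gain, shot
noise and baseline drift.  This module turns them into normalized
positive-going signals, estimates per-pixel quality, optionally smooths
in space and time, and cuts the recording into per-beat windows keyed to
the pacing stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import savgol_filter

from .tissue_sim import VoltageMovie

#: Pre-stimulus margin (ms) in each beat window so the diastolic
#: baseline is observable for APD referencing.
PRE_STIMULUS_MARGIN_MS = 10.0

#: Pixels with amplitude/noise below this are masked out: below ~3 the
#: derivative-based activation detector is unreliable.
SNR_MASK_THRESHOLD = 3.0

#: Movies cleaner than this skip the default smoothing.
SNR_FILTER_THRESHOLD = 20.0
DEFAULT_SPATIAL_SIGMA = 1.0   # px
DEFAULT_TEMPORAL_WINDOW = 5   # frames, Savitzky–Golay


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class PixelMask:
    """Per-pixel analyzability: boolean mask plus the amplitude and noise
    estimates it was derived from."""

    valid: np.ndarray
    amplitude: np.ndarray
    noise: np.ndarray

    @property
    def snr(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.amplitude / self.noise

    @property
    def n_masked(self) -> int:
        return int((~self.valid).sum())


@dataclass
class BeatWindow:
    """One paced beat: the time interval owned by one stimulus.

    ``start``/``end`` are ms from the first frame, half-open
    ``[start, end)``; ``start = stimulus_time - 10 ms`` so a diastolic
    baseline precedes the upstroke.  ``beat_index`` counts beats within
    the window's CL train (0-based; beat 0 is the post-CL-change
    transient).
    """

    cl: float
    stimulus_time: float
    start: float
    end: float
    beat_index: int
    transient: bool = False
    selected: bool = False
    analyzable: bool = True

    def __post_init__(self) -> None:
        if not (self.start <= self.stimulus_time < self.end):
            raise ValueError("window must contain its stimulus time")
        if self.end - self.start > self.cl + 1e-9:
            raise ValueError("window longer than its cycle length")


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def estimate_pixel_quality(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Robust per-pixel (amplitude, noise) estimates.

    Amplitude is the 1st–99th percentile range; noise is the standard
    deviation of the high-frequency component, estimated from
    first differences (median absolute deviation scaled to sigma,
    divided by sqrt(2) since differencing doubles the variance).
    """
    lo = np.percentile(frames, 1, axis=0)
    hi = np.percentile(frames, 99, axis=0)
    amplitude = hi - lo
    d = np.diff(frames, axis=0)
    mad = np.median(np.abs(d - np.median(d, axis=0)), axis=0)
    noise = mad * 1.4826 / np.sqrt(2.0)
    return amplitude, noise


def normalize_movie(movie: VoltageMovie) -> tuple[VoltageMovie, PixelMask]:
    """Polarity-correct and rescale each pixel to [0, 1].

    Fluorescence-down movies are inverted so depolarization is
    positive-going.  Each pixel is linearly rescaled by its robust
    (1st/99th percentile) extrema; flat pixels (amplitude < 2 % of the
    median pixel amplitude) are flagged in the mask and left untouched.
    The rescale is affine, hence idempotent.
    """
    frames = movie.frames
    if movie.polarity == "fluorescence_down":
        frames = -frames

    amplitude, noise = estimate_pixel_quality(frames)
    med_amp = np.median(amplitude)
    if med_amp <= 1e-12:
        raise ValueError("no dynamic signal: movie is flat")
    flat = amplitude <= max(1e-12, 0.02 * med_amp)

    lo = np.percentile(frames, 1, axis=0)
    scale = np.where(flat, 1.0, np.maximum(amplitude, 1e-12))
    offset = np.where(flat, 0.0, lo)
    out = (frames - offset[None, :, :]) / scale[None, :, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise > 0, amplitude / noise, np.inf)
    valid = (~flat) & (snr >= SNR_MASK_THRESHOLD)
    mask = PixelMask(valid=valid, amplitude=amplitude, noise=noise)

    norm = VoltageMovie(frames=out, frame_interval=movie.frame_interval,
                        pixel_pitch=movie.pixel_pitch, polarity="voltage_up",
                        protocol=movie.protocol,
                        stimulus_times=list(movie.stimulus_times),
                        stimulus_cls=list(movie.stimulus_cls))
    return norm, mask


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def filter_movie(movie: VoltageMovie, spatial_sigma: float = DEFAULT_SPATIAL_SIGMA,
                 temporal_window: int = DEFAULT_TEMPORAL_WINDOW) -> VoltageMovie:
    """Gaussian spatial smoothing followed by Savitzky–Golay temporal
    smoothing (order 2).  ``(0, 1)`` settings are the identity and
    return the frames unchanged, bit for bit."""
    if spatial_sigma < 0:
        raise ValueError("spatial_sigma must be >= 0")
    if temporal_window < 1 or temporal_window % 2 == 0:
        raise ValueError("temporal_window must be odd and >= 1")
    if temporal_window > movie.n_frames:
        raise ValueError("temporal window longer than the recording")

    frames = movie.frames
    if spatial_sigma > 0:
        frames = gaussian_filter(frames, sigma=(0.0, spatial_sigma,
                                                spatial_sigma), mode="nearest")
    if temporal_window >= 3:
        frames = savgol_filter(frames, window_length=temporal_window,
                               polyorder=2, axis=0, mode="nearest")
    if frames is movie.frames:
        frames = movie.frames.copy()

    return VoltageMovie(frames=frames, frame_interval=movie.frame_interval,
                        pixel_pitch=movie.pixel_pitch, polarity=movie.polarity,
                        protocol=movie.protocol,
                        stimulus_times=list(movie.stimulus_times),
                        stimulus_cls=list(movie.stimulus_cls))


# --------------------------------------------------------------------------
# Beat segmentation
# --------------------------------------------------------------------------

def segment_beats(movie: VoltageMovie, n_selected: int = 3) -> list[BeatWindow]:
    """Cut the recording into one window per pacing stimulus.

    Each stimulus owns ``[t_stim - 10 ms, t_stim + CL - 10 ms)``; windows
    of one CL train tile without overlap.  The first beat after a CL
    change is marked transient; the next ``n_selected`` consecutive
    beats are marked selected for measurement.  A CL with fewer than two
    delivered beats is flagged unanalyzable (``analyzable=False``)
    rather than raising.
    """
    stim_times = list(movie.stimulus_times)
    if not stim_times:
        raise ValueError("movie has no stimulus times; cannot segment beats")
    cls = list(movie.stimulus_cls)
    if not cls:
        # derive per-stimulus CL from inter-stimulus intervals (the last
        # stimulus inherits the preceding interval)
        if len(stim_times) < 2:
            raise ValueError("cannot derive cycle lengths from a single "
                             "stimulus without protocol metadata")
        diffs = np.diff(stim_times)
        cls = [float(d) for d in diffs] + [float(diffs[-1])]

    windows: list[BeatWindow] = []
    prev_cl = None
    beat_idx = 0
    for t, cl in zip(stim_times, cls):
        if prev_cl is None or cl != prev_cl:
            beat_idx = 0
        windows.append(BeatWindow(
            cl=float(cl), stimulus_time=float(t),
            start=float(t) - PRE_STIMULUS_MARGIN_MS,
            end=float(t) + float(cl) - PRE_STIMULUS_MARGIN_MS,
            beat_index=beat_idx, transient=(beat_idx == 0)))
        beat_idx += 1
        prev_cl = cl

    # truncate / invalidate windows that run past the recording
    for w in windows:
        if w.end > movie.duration + 1e-9:
            w.analyzable = False

    for cl in {w.cl for w in windows}:
        train = [w for w in windows if w.cl == cl]
        if len(train) < 2:
            for w in train:
                w.analyzable = False
            warnings.warn(f"cycle length {cl} ms has fewer than 2 beats; "
                          "flagged unanalyzable")
            continue
        candidates = [w for w in train if not w.transient and w.analyzable]
        for w in candidates[:n_selected]:
            w.selected = True
    return windows


def analyzable_cls(windows: list[BeatWindow]) -> list[float]:
    """Cycle lengths with at least one selected beat, in encounter order."""
    seen: list[float] = []
    for w in windows:
        if w.selected and w.cl not in seen:
            seen.append(w.cl)
    return seen
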