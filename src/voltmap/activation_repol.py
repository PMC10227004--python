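"""Per-pixel activation time and APD80 within beat windows.

Activation is the instant of steepest phase-0 upstroke: the peak of the
central-difference first derivative, refined below the frame interval
by parabolic interpolation of the discrete derivative maximum.  APD80
runs from activation to the first post-peak instant the signal recovers
to 20 % of its beat amplitude (peak minus pre-stimulus baseline), with
linear interpolation between samples.  The diastolic interval is the
pacing cycle length minus APD80.

Maps are assembled per cycle length by averaging up to three selected
consecutive beats pixel-wise, the standard beat-averaging convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import BeatWindow, PixelMask
from .tissue_sim import VoltageMovie

#: A detected upstroke must reach this fraction of the pixel's range.
MIN_UPSTROKE_AMPLITUDE = 0.3
#: ... and its peak derivative must exceed this multiple of the
#: baseline (pre-stimulus) derivative noise.
MIN_DERIVATIVE_SNR = 5.0
#: Fraction of amplitude remaining at the APD80 repolarization level.
REPOL_LEVEL = 0.2
#: Default number of beats averaged per cycle length.
N_BEATS_AVERAGED = 3
#: Cycle lengths short enough that beats routinely fuse are excluded
#: from APD analysis unless explicitly overridden.
APD_MIN_CL_MS = 200.0


@dataclass
class ActivationMap:
    """Per-pixel activation time (ms relative to the window start) for one
    CL, beat-averaged; NaN marks invalid pixels."""

    values: np.ndarray
    valid: np.ndarray
    cl: float
    pixel_pitch: float
    beat_indices: tuple[int, ...] = ()
    window_length: float = 0.0
    low_quality: bool = False


@dataclass
class APDMap:
    """Per-pixel APD80 (ms) for one CL, beat-averaged; NaN = invalid."""

    values: np.ndarray
    valid: np.ndarray
    cl: float
    pixel_pitch: float
    beat_indices: tuple[int, ...] = ()
    low_quality: bool = False


# --------------------------------------------------------------------------
# Vectorized per-beat measurement
# --------------------------------------------------------------------------

def measure_beat_fields(frames: np.ndarray, frame_interval: float,
                        window: BeatWindow,
                        pixel_range: np.ndarray | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Activation and APD80 fields for one beat window, vectorized over
    all pixels.

    Returns ``(activation, apd80)`` as (rows, cols) float arrays;
    activation is ms relative to ``window.start``; invalid pixels are
    NaN in both.
    """
    n_frames = frames.shape[0]
    i0 = max(int(math.ceil(window.start / frame_interval)), 0)
    i1 = min(int(math.floor(window.end / frame_interval)) + 1, n_frames)
    if i1 - i0 < 7:
        shape = frames.shape[1:]
        nan = np.full(shape, np.nan)
        return nan, nan.copy()
    sub = frames[i0:i1]  # (T, R, C)
    t_rel = (np.arange(i0, i1) * frame_interval) - window.start
    stim_rel = window.stimulus_time - window.start

    # strictly pre-stimulus samples only: pixels close to the stimulus
    # site can already be rising at the stimulus-time sample
    n_base = int(np.searchsorted(t_rel, stim_rel, side="left"))
    n_base = max(n_base, 1)
    baseline = sub[:n_base].mean(axis=0)

    # central-difference derivative; search from the stimulus onward
    deriv = np.empty_like(sub)
    deriv[1:-1] = (sub[2:] - sub[:-2]) / (2.0 * frame_interval)
    deriv[0] = (sub[1] - sub[0]) / frame_interval
    deriv[-1] = (sub[-1] - sub[-2]) / frame_interval

    search0 = max(n_base - 1, 1)
    d_search = deriv[search0:-1]  # keep parabola neighbours in range
    k = np.argmax(d_search, axis=0) + search0
    rows, cols = np.indices(k.shape)
    d0 = deriv[k - 1, rows, cols]
    d1 = deriv[k, rows, cols]
    d2 = deriv[k + 1, rows, cols]
    denom = d0 - 2.0 * d1 + d2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (d0 - d2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)  # never move past a neighbouring frame
    act_rel = t_rel[k] + shift * frame_interval

    # beat amplitude and validity
    peak_idx = np.argmax(
        np.where(np.arange(len(t_rel))[:, None, None] >= k[None], sub, -np.inf),
        axis=0)
    peak = sub[peak_idx, rows, cols]
    amplitude = peak - baseline
    if pixel_range is None:
        pixel_range = frames.max(axis=0) - frames.min(axis=0)
    base_dnoise = deriv[:max(n_base - 1, 1)].std(axis=0)
    dpeak = d1
    valid = (amplitude >= MIN_UPSTROKE_AMPLITUDE * np.maximum(pixel_range, 1e-12))
    valid &= dpeak > 0
    valid &= dpeak >= MIN_DERIVATIVE_SNR * base_dnoise
    valid &= act_rel > stim_rel - frame_interval

    # APD80: first drop below baseline + 0.2*amplitude after the peak
    thr = baseline + REPOL_LEVEL * amplitude
    after_peak = np.arange(len(t_rel))[:, None, None] > peak_idx[None]
    below = (sub <= thr[None]) & after_peak
    crossed = below.any(axis=0)
    j = np.argmax(below, axis=0)  # first True where crossed
    jm = np.maximum(j - 1, 0)
    y1 = sub[jm, rows, cols]
    y2 = sub[j, rows, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(np.abs(y1 - y2) > 1e-12,
                        (y1 - thr) / (y1 - y2), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    t80 = t_rel[jm] + frac * frame_interval
    apd = t80 - act_rel

    valid_apd = valid & crossed & (apd > 0)
    act_out = np.where(valid, act_rel, np.nan)
    apd_out = np.where(valid_apd, apd, np.nan)
    return act_out, apd_out


# --------------------------------------------------------------------------
# Scalar trace operations
# --------------------------------------------------------------------------

def activation_time(trace: np.ndarray, window: BeatWindow,
                    frame_interval: float) -> float:
    """Steepest-upstroke time (ms from the recording start) of one pixel
    trace within a beat window; NaN if no valid upstroke."""
    act, _ = measure_beat_fields(np.asarray(trace, float)[:, None, None],
                                 frame_interval, window)
    val = float(act[0, 0])
    return val + window.start if np.isfinite(val) else float("nan")


def apd80(trace: np.ndarray, t_act: float, window: BeatWindow,
          frame_interval: float) -> float:
    """APD80 (ms) of one pixel trace: 80 %-repolarization time minus the
    given activation time ``t_act`` (ms from recording start).

    NaN (missing) when the signal never recovers to the 20 % level
    inside the window — the fused-beat case.
    """
    if not (window.start < t_act < window.end):
        raise ValueError("t_act must lie inside the beat window")
    act, apd = measure_beat_fields(np.asarray(trace, float)[:, None, None],
                                   frame_interval, window)
    a = float(apd[0, 0])
    if not np.isfinite(a):
        return float("nan")
    # measure from the caller's activation time, same 80% crossing
    t80 = float(act[0, 0]) + window.start + a
    return t80 - t_act


def beat_average(values, n_beats: int = N_BEATS_AVERAGED
                 ) -> tuple[float, int]:
    """Missing-tolerant arithmetic mean over up to ``n_beats`` beat
    values; returns ``(mean, n_contributing)`` with NaN/0 when no beat
    is valid."""
    vals = [v for v in list(values)[:n_beats]
            if v is not None and np.isfinite(v)]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def diastolic_interval(cl: float, apd80_ms: float) -> float:
    """DI = cycle length minus APD80 (ms); both must be positive with
    APD80 < CL, otherwise the restitution pair is impossible."""
    if not (0 < apd80_ms < cl):
        raise ValueError(f"need 0 < apd80 ({apd80_ms}) < cl ({cl}); "
                         "diastolic interval undefined")
    return cl - apd80_ms


# --------------------------------------------------------------------------
# Map assembly
# --------------------------------------------------------------------------

def build_maps(movie: VoltageMovie, windows: list[BeatWindow],
               mask: PixelMask | None = None,
               roi: tuple[int, int, int, int] | None = None,
               n_beats: int = N_BEATS_AVERAGED,
               apd_min_cl: float = APD_MIN_CL_MS,
               ) -> dict[float, tuple[ActivationMap, APDMap]]:
    """Beat-averaged activation and APD80 maps for every analyzable CL.

    Pixels masked out in ``mask`` are NaN.  APD maps are produced only
    for CLs >= ``apd_min_cl`` (shorter CLs routinely fuse beats; pass 0
    to override); activation maps are produced for every CL.  A CL
    whose ROI is more than half invalid is flagged ``low_quality``.
    """
    pixel_range = movie.frames.max(axis=0) - movie.frames.min(axis=0)
    out: dict[float, tuple[ActivationMap, APDMap]] = {}
    for cl in _ordered_cls(windows):
        sel = [w for w in windows if w.cl == cl and w.selected][:n_beats]
        if not sel:
            continue
        acts, apds = [], []
        for w in sel:
            a, p = measure_beat_fields(movie.frames, movie.frame_interval, w,
                                       pixel_range=pixel_range)
            acts.append(a)
            apds.append(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            act_mean = np.nanmean(np.stack(acts), axis=0)
            apd_mean = np.nanmean(np.stack(apds), axis=0)
        if mask is not None:
            act_mean = np.where(mask.valid, act_mean, np.nan)
            apd_mean = np.where(mask.valid, apd_mean, np.nan)
        if cl < apd_min_cl:
            apd_mean = np.full_like(apd_mean, np.nan)

        act_valid = np.isfinite(act_mean)
        apd_valid = np.isfinite(apd_mean)
        lowq = False
        if roi is not None:
            r0, c0, r1, c1 = roi
            lowq = act_valid[r0:r1, c0:c1].mean() < 0.5
        beat_idx = tuple(w.beat_index for w in sel)
        amap = ActivationMap(values=act_mean, valid=act_valid, cl=cl,
                             pixel_pitch=movie.pixel_pitch,
                             beat_indices=beat_idx,
                             window_length=sel[0].end - sel[0].start,
                             low_quality=lowq)
        pmap = APDMap(values=apd_mean, valid=apd_valid, cl=cl,
                      pixel_pitch=movie.pixel_pitch,
                      beat_indices=beat_idx, low_quality=lowq)
        out[cl] = (amap, pmap)
    return out


def roi_stats(map_values: np.ndarray,
              roi: tuple[int, int, int, int]) -> tuple[float, float, int]:
    """(mean, sample SD, n_valid) over the ROI (half-open row/col rect)."""
    r0, c0, r1, c1 = roi
    patch = map_values[r0:r1, c0:c1]
    vals = patch[np.isfinite(patch)]
    if vals.size == 0:
        return float("nan"), float("nan"), 0
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return float(np.mean(vals)), sd, int(vals.size)


def default_roi(shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Centered rectangle covering ~1/3 of the field, emulating the
    analysis rectangle placed on the anterior LV free wall."""
    rows, cols = shape
    h, w = rows // 3, cols // 3
    r0 = (rows - h) // 2
    c0 = (cols - w) // 2
    return r0, c0, r0 + h, c0 + w


def _ordered_cls(windows: list[BeatWindow]) -> list[float]:
    seen: list[float] = []
    for w in windows:
        if w.cl not in seen:
            seen.append(w.cl)
    return seen
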