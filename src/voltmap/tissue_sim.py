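"""Synthetic optical-mapping movies of paced cardiac tissue.

Two generators share one output contract (:class:`VoltageMovie` plus a
:class:`GroundTruth` oracle channel):

``plane_wave_movie``
    A closed-form travelling plane wave with an analytically known
    conduction velocity and APD80 at every pixel.  Used as the exact
    oracle for the measurement chain.

``simulate_tissue``
    A two-variable phenomenological excitable-medium model
    (Aliev–Panfilov class: cubic excitation + slow recovery gate,
    isotropic diffusion, no-flux boundaries) paced by a line stimulus.
    Reproduces the qualitative electrophysiology the analysis side
    measures — finite conduction velocity, APD restitution, and
    phenotype differences — without ionic detail.

Geometry and protocol defaults emulate a standard panoramic-mapping rig:
a 128 x 128 photodiode/CMOS grid over a 30 x 30 mm field of view, 2 ms
frame interval, 1000 frames (2 s) per recording, constant pacing at
cycle lengths 400/300/250/200/150 ms with 3 ms stimulus pulses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# Configuration: acquisition geometry, model constants, phenotype presets
# --------------------------------------------------------------------------

#: Field of view (mm) and detector grid of the emulated rig.
FIELD_OF_VIEW_MM = 30.0
GRID_ROWS_DEFAULT = 128
GRID_COLS_DEFAULT = 128
PIXEL_PITCH_DEFAULT = FIELD_OF_VIEW_MM / GRID_COLS_DEFAULT  # 0.234375 mm/px

#: Acquisition timing.
FRAME_INTERVAL_MS = 2.0
FRAMES_PER_RECORDING = 1000

#: Pacing defaults (ms).
CYCLE_LENGTHS_DEFAULT = (400.0, 300.0, 250.0, 200.0, 150.0)
STIMULUS_DURATION_MS = 3.0
BEATS_PER_CL_DEFAULT = 4  # first beat discarded as transient, next 3 measured

#: Aliev–Panfilov reaction constants (dimensionless).
AP_A = 0.15
AP_MU1 = 0.2
AP_MU2 = 0.3
AP_EPS0_BASE = 0.002

#: Time scale: ms of real time per model time unit.  Chosen once so the
#: control preset lands in the physiological rabbit range (APD80 ~ 75 ms
#: at CL 400 ms); see docs/methods.md.
TIME_SCALE_MS = 2.6

#: Internal integration step (ms); must resolve the upstroke well below
#: the 2 ms frame interval.
DT_MS = 0.05

#: Stimulus current (model units of du/dt per model time unit).
STIM_AMPLITUDE = 10.0
STIM_WIDTH_PX = 3  # columns driven by the line stimulus at the left edge

#: Phenotype presets.  The failing-heart preset slows conduction
#: (diffusivity x0.4) and prolongs repolarization (repol_rate x0.6),
#: the direction observed in tachycardia-induced cardiomyopathy.
PHENOTYPES: dict[str, dict[str, float]] = {
    "control": {"diffusivity": 0.40, "excitability": 8.0, "repol_rate": 0.70},
    "hf": {"diffusivity": 0.16, "excitability": 8.0, "repol_rate": 0.42},
}


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueParams:
    """Tissue/model parameters for one simulated preparation.

    Parameters
    ----------
    grid_rows, grid_cols
        Detector grid size (>= 16 each).
    pixel_pitch
        mm per pixel.
    diffusivity
        Isotropic voltage diffusivity, mm^2/ms.  Conduction velocity
        scales as sqrt(diffusivity) (monodomain scaling).
    excitability
        Dimensionless cubic-reaction gain (Aliev–Panfilov ``k``).
    repol_rate
        Dimensionless multiplier on the recovery-gate rate (both the
        baseline rate and its voltage-dependent part); smaller values
        prolong APD.
    phenotype_label
        ``"control"`` or ``"hf"``.
    """

    grid_rows: int = GRID_ROWS_DEFAULT
    grid_cols: int = GRID_COLS_DEFAULT
    pixel_pitch: float = PIXEL_PITCH_DEFAULT
    diffusivity: float = PHENOTYPES["control"]["diffusivity"]
    excitability: float = PHENOTYPES["control"]["excitability"]
    repol_rate: float = PHENOTYPES["control"]["repol_rate"]
    phenotype_label: str = "control"

    def __post_init__(self) -> None:
        if self.grid_rows < 16 or self.grid_cols < 16:
            raise ValueError("grid dimensions must be >= 16")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be > 0")
        if self.repol_rate <= 0:
            raise ValueError("repol_rate must be > 0")
        if self.phenotype_label not in ("control", "hf"):
            raise ValueError("phenotype_label must be 'control' or 'hf'")

    @classmethod
    def preset(cls, phenotype: str, grid_rows: int = GRID_ROWS_DEFAULT,
               grid_cols: int = GRID_COLS_DEFAULT) -> "TissueParams":
        """Build parameters from a named phenotype preset."""
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}; "
                             f"known: {sorted(PHENOTYPES)}")
        p = PHENOTYPES[phenotype]
        return cls(grid_rows=grid_rows, grid_cols=grid_cols,
                   pixel_pitch=FIELD_OF_VIEW_MM / grid_cols,
                   diffusivity=p["diffusivity"],
                   excitability=p["excitability"],
                   repol_rate=p["repol_rate"],
                   phenotype_label=phenotype)


@dataclass(frozen=True)
class PacingProtocol:
    """Constant-pacing protocol: trains of stimuli at fixed cycle lengths.

    ``cycle_lengths`` are kept in the order given (conventionally fast
    to slow or slow to fast as the operator programmed them); each CL
    train contains ``beats_per_cl`` stimuli.
    """

    cycle_lengths: tuple[float, ...] = CYCLE_LENGTHS_DEFAULT
    beats_per_cl: int = BEATS_PER_CL_DEFAULT
    stimulus_duration: float = STIMULUS_DURATION_MS
    stimulus_site: str = "left_edge"
    start_time: float = 20.0  # ms of baseline before the first stimulus

    def __post_init__(self) -> None:
        if not self.cycle_lengths:
            raise ValueError("at least one cycle length required")
        if any(cl <= 0 for cl in self.cycle_lengths):
            raise ValueError("all cycle lengths must be > 0")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be > 0")
        if self.beats_per_cl < 1:
            raise ValueError("beats_per_cl must be >= 1")
        object.__setattr__(self, "cycle_lengths",
                           tuple(float(c) for c in self.cycle_lengths))

    def schedule(self) -> list[tuple[float, float]]:
        """Return ``[(stimulus_time_ms, cycle_length_ms), ...]``.

        Trains are laid back to back: after the last stimulus of a
        train one full cycle of that CL elapses before the next train
        starts, so every beat owns a complete window.
        """
        out: list[tuple[float, float]] = []
        t = self.start_time
        for cl in self.cycle_lengths:
            for _ in range(self.beats_per_cl):
                out.append((t, cl))
                t += cl
        return out

    @property
    def stimulus_times(self) -> list[float]:
        return [t for t, _ in self.schedule()]

    @property
    def total_duration(self) -> float:
        """ms from recording start to the end of the last beat window."""
        sched = self.schedule()
        return sched[-1][0] + sched[-1][1]


@dataclass
class VoltageMovie:
    """A frame stack with acquisition metadata — the common currency of
    simulation and analysis.

    ``frames`` is (time, row, col), floating point.  ``polarity`` is
    ``"voltage_up"`` (depolarization increases the signal) or
    ``"fluorescence_down"`` (voltage-sensitive-dye convention:
    fluorescence falls on depolarization).
    """

    frames: np.ndarray
    frame_interval: float = FRAME_INTERVAL_MS
    pixel_pitch: float = PIXEL_PITCH_DEFAULT
    polarity: str = "voltage_up"
    protocol: PacingProtocol | None = None
    stimulus_times: list[float] = field(default_factory=list)
    stimulus_cls: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (time, row, col)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if self.polarity not in ("voltage_up", "fluorescence_down"):
            raise ValueError("polarity must be voltage_up|fluorescence_down")
        st = np.asarray(self.stimulus_times, dtype=float)
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise ValueError("stimulus_times must be strictly increasing")
        if self.stimulus_cls and len(self.stimulus_cls) != len(self.stimulus_times):
            raise ValueError("stimulus_cls must match stimulus_times")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Recording span in ms (n_frames x frame_interval)."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in ms from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruthBeat:
    """Oracle fields for one beat: per-pixel activation time (ms, relative
    to the beat window start) and APD80 (ms)."""

    cl: float
    beat_index: int
    stimulus_time: float
    activation: np.ndarray
    apd80: np.ndarray
    captured: bool = True


@dataclass
class GroundTruth:
    """Oracle channel accompanying a synthetic movie (test plumbing)."""

    beats: list[GroundTruthBeat]
    plane_cv: float | None = None  # cm/s, plane-wave generator only

    def beats_for_cl(self, cl: float) -> list[GroundTruthBeat]:
        return [b for b in self.beats if b.cl == cl]

    def mean_apd80(self, cl: float) -> float:
        """Grand mean ground-truth APD80 (ms) over captured beats of a CL."""
        vals = [np.nanmean(b.apd80) for b in self.beats_for_cl(cl) if b.captured]
        if not vals:
            return float("nan")
        return float(np.mean(vals))


# --------------------------------------------------------------------------
# Plane-wave generator (analytic oracle)
# --------------------------------------------------------------------------

#: Fraction of the raised-cosine repolarization elapsed at the 20 %
#: level: solve (1 + cos(pi x)) / 2 = 0.2  ->  x = acos(-0.6) / pi.
_RC_X20 = math.acos(-0.6) / math.pi


def _plane_waveform_params(apd80: float, cl_min: float,
                           rise_ms: float = 1.5) -> tuple[float, float]:
    """Geometry of the stereotyped action potential.

    A half-cosine upstroke of width ``rise_ms`` (steepest slope at time
    0) peaks at ``t0 = rise/2`` and hands over, C1-continuously, to a
    raised-cosine repolarization that reaches 0 at ``t_zero`` with zero
    slope (compact support: consecutive beats never overlap).  The
    raised cosine passes its 20 % level at the fixed fraction
    ``_RC_X20`` of its span, so ``t_zero`` is chosen to put the 80 %
    crossing exactly ``apd80`` ms after the steepest upstroke.
    Returns ``(t0, t_zero)``.
    """
    t0 = rise_ms / 2.0
    if not apd80 > t0 + 2.0:
        raise ValueError(f"apd80={apd80} too short for the waveform template")
    t_zero = t0 + (apd80 - t0) / _RC_X20
    # window is [stim-10, stim+CL-10): the AP must end inside its window
    if t_zero > cl_min - 15.0:
        raise ValueError(
            f"apd80={apd80} ms does not fit in the shortest cycle length "
            f"{cl_min} ms (beats would fuse)")
    return t0, t_zero


def _plane_waveform(tau: np.ndarray, t0: float, t_zero: float,
                    rise_ms: float = 1.5) -> np.ndarray:
    """Evaluate the stereotyped action potential at times ``tau`` (ms)
    relative to the steepest-upstroke instant."""
    out = np.zeros_like(tau, dtype=np.float64)
    r2 = rise_ms / 2.0
    up = (tau >= -r2) & (tau < r2)
    out[up] = 0.5 * (1.0 + np.sin(np.pi * tau[up] / rise_ms))
    dec = (tau >= r2) & (tau < t_zero)
    out[dec] = 0.5 * (1.0 + np.cos(np.pi * (tau[dec] - t0) / (t_zero - t0)))
    return out


def plane_wave_movie(cv: float, apd80: float,
                     params: TissueParams | None = None,
                     protocol: PacingProtocol | None = None,
                     ) -> tuple[VoltageMovie, GroundTruth]:
    """Closed-form movie of a plane wave sweeping left to right.

    Parameters
    ----------
    cv
        Conduction velocity in cm/s (> 0).
    apd80
        Action potential duration at 80 % repolarization, ms; must be
        shorter than the shortest cycle length or beats would fuse.

    Returns
    -------
    movie, truth
        ``movie.polarity`` is ``voltage_up`` (add acquisition noise and
        dye polarity with :func:`add_acquisition_noise`).  ``truth``
        holds the exact per-beat activation and APD80 fields and the
        plane conduction velocity.
    """
    if cv <= 0:
        raise ValueError("cv must be > 0")
    params = params or TissueParams()
    protocol = protocol or PacingProtocol(cycle_lengths=(400.0,))
    cl_min = min(protocol.cycle_lengths)
    if apd80 >= cl_min:
        raise ValueError("apd80 must be shorter than the shortest cycle "
                         "length (beats would fuse)")
    t0, t_zero = _plane_waveform_params(apd80, cl_min)

    v_mm_ms = cv / 100.0  # 100 cm/s == 1 mm/ms
    cols = np.arange(params.grid_cols, dtype=np.float64)
    latency = cols * params.pixel_pitch / v_mm_ms  # ms, per column

    sched = protocol.schedule()
    # the rig records at least 2 s (1000 frames) per acquisition
    duration = max(sched[-1][0] + sched[-1][1],
                   FRAMES_PER_RECORDING * FRAME_INTERVAL_MS)
    n_frames = int(math.ceil(duration / FRAME_INTERVAL_MS))
    t = np.arange(n_frames) * FRAME_INTERVAL_MS

    signal = np.zeros((n_frames, params.grid_cols), dtype=np.float64)
    for stim_t, _cl in sched:
        tau = t[:, None] - (stim_t + latency[None, :])
        signal += _plane_waveform(tau, t0, t_zero)
    frames = np.repeat(signal[:, None, :], params.grid_rows, axis=1)

    movie = VoltageMovie(frames=frames, frame_interval=FRAME_INTERVAL_MS,
                         pixel_pitch=params.pixel_pitch, polarity="voltage_up",
                         protocol=protocol,
                         stimulus_times=[st for st, _ in sched],
                         stimulus_cls=[cl for _, cl in sched])

    beats: list[GroundTruthBeat] = []
    act_row = latency[None, :].repeat(params.grid_rows, axis=0)
    apd_field = np.full((params.grid_rows, params.grid_cols), float(apd80))
    for i, (stim_t, cl) in enumerate(sched):
        beat_idx = i - next(k for k, (_, c) in enumerate(sched) if c == cl)
        # activation relative to window start (stim - 10 ms margin)
        beats.append(GroundTruthBeat(cl=cl, beat_index=beat_idx,
                                     stimulus_time=stim_t,
                                     activation=act_row + 10.0,
                                     apd80=apd_field.copy()))
    return movie, GroundTruth(beats=beats, plane_cv=float(cv))


# --------------------------------------------------------------------------
# Reaction–diffusion simulator
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _integrate_ap(u, v, het, n_steps, dt, d_over_h2, k, a, eps0, mu1, mu2,
                  inv_ts, stim_start, stim_end, stim_amp, stim_cols,
                  out, out_every):
    """Explicit-Euler integration of the two-variable excitable medium.

    5-point Laplacian with no-flux (mirror) boundaries; the line
    stimulus drives ``stim_cols`` left-edge columns between the step
    indices in ``stim_start``/``stim_end``.  ``u`` frames are written to
    ``out`` every ``out_every`` steps.
    """
    rows, cols = u.shape
    n_stim = stim_start.shape[0]
    si = 0
    frame = 0
    for step in range(n_steps):
        if frame < out.shape[0] and step % out_every == 0:
            for i in range(rows):
                for j in range(cols):
                    out[frame, i, j] = u[i, j]
            frame += 1
        while si < n_stim and step >= stim_end[si]:
            si += 1
        stim_on = si < n_stim and stim_start[si] <= step < stim_end[si]
        for i in range(rows):
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < rows - 1 else rows - 2
            for j in range(cols):
                jm = j - 1 if j > 0 else 1
                jp = j + 1 if j < cols - 1 else cols - 2
                uij = u[i, j]
                vij = v[i, j]
                lap = (u[im, j] + u[ip, j] + u[i, jm] + u[i, jp]
                       - 4.0 * uij)
                kk = k * het[i, j]
                react = kk * uij * (uij - a) * (1.0 - uij) - uij * vij
                du = d_over_h2 * lap + react * inv_ts
                if stim_on and j < stim_cols:
                    du += stim_amp * inv_ts
                eps = eps0 + mu1 * vij / (uij + mu2)
                dv = eps * (-vij - kk * uij * (uij - a - 1.0)) * inv_ts
                u[i, j] = uij + dt * du
                v[i, j] = vij + dt * dv
    return frame


def simulate_tissue(params: TissueParams | None = None,
                    protocol: PacingProtocol | None = None,
                    duration: float | None = None,
                    seed: int = 0,
                    compute_ground_truth: bool = True,
                    ) -> tuple[VoltageMovie, GroundTruth]:
    """Simulate a paced 2-D sheet and record it like the optical rig.

    The transmembrane variable of an Aliev–Panfilov-class model is
    integrated with an internal step of {DT} ms and resampled to the
    2 ms frame interval.  A line stimulus at the left edge fires at each
    protocol stimulus time.  A seeded, smoothed ±2 % excitability
    heterogeneity field makes preparations individually distinct while
    keeping the run fully deterministic given (params, protocol, seed).

    Ground-truth activation and APD80 fields are measured from the
    noise-free resampled frames with the same steepest-upstroke /
    80 %-recovery definitions the analysis chain uses.
    """
    params = params or TissueParams()
    protocol = protocol or PacingProtocol(cycle_lengths=(400.0,),
                                          beats_per_cl=4)
    sched = protocol.schedule()
    if duration is None:
        duration = max(sched[-1][0] + sched[-1][1],
                       FRAMES_PER_RECORDING * FRAME_INTERVAL_MS)
    longest = max(protocol.cycle_lengths)
    need = protocol.start_time + 4 * longest
    n_longest = sum(1 for _, c in sched if c == longest)
    if n_longest >= 4 and duration < need - 1e-9:
        raise ValueError(
            f"duration {duration} ms does not cover 4 beats of the longest "
            f"cycle length ({longest} ms); need >= {need} ms")

    # explicit-Euler diffusion stability: dt <= h^2 / (4 D), with margin;
    # substeps divide the frame interval exactly so frames land on time
    d_over_h2 = params.diffusivity / params.pixel_pitch ** 2
    dt_max = min(DT_MS, 0.9 * 0.25 / d_over_h2)
    out_every = int(math.ceil(FRAME_INTERVAL_MS / dt_max))
    dt = FRAME_INTERVAL_MS / out_every
    n_frames = int(math.floor(duration / FRAME_INTERVAL_MS))
    n_steps = n_frames * out_every

    rng = np.random.default_rng(seed)
    het = 1.0 + 0.02 * _smooth_noise(params.grid_rows, params.grid_cols, rng)

    u = np.zeros((params.grid_rows, params.grid_cols), dtype=np.float64)
    v = np.zeros_like(u)
    out = np.empty((n_frames, params.grid_rows, params.grid_cols),
                   dtype=np.float64)
    stim_start = np.array([int(round(t / dt)) for t, _ in sched],
                          dtype=np.int64)
    stim_end = np.array(
        [int(round((t + protocol.stimulus_duration) / dt)) for t, _ in sched],
        dtype=np.int64)

    _integrate_ap(u, v, het, n_steps, dt, d_over_h2,
                  params.excitability, AP_A,
                  AP_EPS0_BASE * params.repol_rate,
                  AP_MU1 * params.repol_rate, AP_MU2,
                  1.0 / TIME_SCALE_MS, stim_start, stim_end,
                  STIM_AMPLITUDE, STIM_WIDTH_PX, out, out_every)

    if not np.all(np.isfinite(out)):
        raise FloatingPointError("simulation blew up (non-finite state); "
                                 "check diffusivity/step-size settings")

    movie = VoltageMovie(frames=out, frame_interval=FRAME_INTERVAL_MS,
                         pixel_pitch=params.pixel_pitch,
                         polarity="voltage_up", protocol=protocol,
                         stimulus_times=[t for t, _ in sched],
                         stimulus_cls=[c for _, c in sched])
    truth = (_ground_truth_from_movie(movie) if compute_ground_truth
             else GroundTruth(beats=[]))
    return movie, truth


def _smooth_noise(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude spatially smooth noise field in [-1, 1]."""
    from scipy.ndimage import gaussian_filter
    raw = rng.standard_normal((rows, cols))
    sm = gaussian_filter(raw, sigma=6.0, mode="reflect")
    peak = np.max(np.abs(sm))
    return sm / peak if peak > 0 else sm


def _ground_truth_from_movie(movie: VoltageMovie) -> GroundTruth:
    """Measure oracle activation/APD80 fields from noise-free frames using
    the same event definitions as the analysis chain."""
    # Imported here: analysis modules depend on the types defined above.
    from .preprocess import segment_beats
    from .activation_repol import measure_beat_fields

    windows = segment_beats(movie)
    beats = []
    for w in windows:
        act, apd = measure_beat_fields(movie.frames, movie.frame_interval, w)
        # capture check: did the wave reach the far quarter of the sheet?
        far = act[:, 3 * act.shape[1] // 4:]
        captured = bool(np.isfinite(far).mean() > 0.5)
        beats.append(GroundTruthBeat(cl=w.cl, beat_index=w.beat_index,
                                     stimulus_time=w.stimulus_time,
                                     activation=act, apd80=apd,
                                     captured=captured))
    return GroundTruth(beats=beats, plane_cv=None)


# --------------------------------------------------------------------------
# Acquisition noise
# --------------------------------------------------------------------------

def add_acquisition_noise(movie: VoltageMovie, snr: float,
                          drift_amplitude: float = 0.02,
                          seed: int = 0,
                          flip_polarity: bool = True) -> VoltageMovie:
    """Emulate dye/camera acquisition on a clean movie.

    Adds per-pixel white noise with standard deviation
    ``signal amplitude / snr`` (amplitude = robust per-pixel 1st–99th
    percentile range), a slow sinusoidal baseline drift of fractional
    amplitude ``drift_amplitude``, and (by default) flips the signal to
    the voltage-sensitive-dye convention where fluorescence *falls* on
    depolarization.  Deterministic given ``seed``.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if drift_amplitude < 0:
        raise ValueError("drift_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    frames = movie.frames.copy()
    lo = np.percentile(frames, 1, axis=0)
    hi = np.percentile(frames, 99, axis=0)
    amp = np.maximum(hi - lo, 1e-12)

    noise = rng.standard_normal(frames.shape) * (amp / snr)[None, :, :]
    t = movie.times
    if drift_amplitude > 0:
        period = rng.uniform(1000.0, 3000.0, size=frames.shape[1:])
        phase = rng.uniform(0, 2 * np.pi, size=frames.shape[1:])
        drift = (drift_amplitude * amp)[None, :, :] * np.sin(
            2 * np.pi * t[:, None, None] / period[None, :, :]
            + phase[None, :, :])
    else:
        drift = 0.0
    frames = frames + noise + drift

    polarity = movie.polarity
    if flip_polarity and polarity == "voltage_up":
        # reflect around the mid-range so depolarization darkens the pixel
        mid = (frames.max() + frames.min()) / 2.0
        frames = 2.0 * mid - frames
        polarity = "fluorescence_down"

    return VoltageMovie(frames=frames, frame_interval=movie.frame_interval,
                        pixel_pitch=movie.pixel_pitch, polarity=polarity,
                        protocol=movie.protocol,
                        stimulus_times=list(movie.stimulus_times),
                        stimulus_cls=list(movie.stimulus_cls))


def simulate_cohort(phenotype: str, n_subjects: int,
                    protocol: PacingProtocol | None = None,
                    grid: int = GRID_ROWS_DEFAULT,
                    snr: float = 20.0,
                    seed: int = 0,
                    ) -> list[tuple[str, VoltageMovie, GroundTruth]]:
    """Simulate a cohort of individually distinct preparations.

    Subjects share a phenotype preset but differ by a small seeded
    biological jitter (diffusivity +/- 5 %, repolarization rate
    +/- 3 %, 1-sigma) plus independent acquisition noise, emulating
    animal-to-animal variability.  Returns
    ``[(subject_id, noisy_movie, ground_truth), ...]``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocol = protocol or PacingProtocol()
    rng = np.random.default_rng(seed)
    base = TissueParams.preset(phenotype, grid_rows=grid, grid_cols=grid)
    out = []
    for i in range(n_subjects):
        params = replace(
            base,
            diffusivity=base.diffusivity * float(1 + 0.05 * rng.standard_normal()),
            repol_rate=base.repol_rate * float(1 + 0.03 * rng.standard_normal()))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        movie, truth = simulate_tissue(params, protocol, seed=sub_seed)
        noisy = add_acquisition_noise(movie, snr=snr, seed=sub_seed + 1)
        out.append((f"{phenotype}_{i}", noisy, truth))
    return out


simulate_tissue.__doc__ = simulate_tissue.__doc__.replace("{DT}", str(DT_MS))
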