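"""Conduction velocity and isochrone maps from activation maps.

Conduction velocity uses the two-point (single-vector) method: the
Euclidean distance between two probe pixels on the apparent
longitudinal propagation axis, divided by their activation-time
difference.  Probe placement is either manual or automatic; the
automatic mode operationalizes "apparent longitudinal axis" as the mean
direction of the activation-time gradient over the region of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure

from .activation_repol import ActivationMap, default_roi

#: Minimum activation-time difference (ms) for a stable velocity — a
#: quarter frame after sub-sample interpolation; below this the
#: quantization error dominates.
MIN_DELTA_T_MS = 0.5

#: Probe spans at least this fraction of the ROI extent along the axis.
MIN_PROBE_SPAN = 0.6

#: Gradient directions with circular variance above this are too
#: incoherent for automatic probe placement.
MAX_CIRCULAR_VARIANCE = 0.5


@dataclass(frozen=True)
class VectorProbe:
    """Two probe pixels (row, col) defining the measurement vector."""

    p1: tuple[int, int]
    p2: tuple[int, int]
    pixel_pitch: float
    selection_mode: str = "manual"

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError("probe points must differ")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.selection_mode not in ("manual", "auto"):
            raise ValueError("selection_mode must be manual|auto")

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.p1[0] - self.p2[0],
                              self.p1[1] - self.p2[1]))


@dataclass
class CVMeasurement:
    """Single-vector conduction velocity with its audit trail."""

    cv_cm_s: float
    t1_ms: float
    t2_ms: float
    distance_mm: float
    probe: VectorProbe


def single_vector_cv(act_map: ActivationMap, probe: VectorProbe,
                     full: bool = False, endpoint_halfwidth: int = 4):
    """Two-point conduction velocity in cm/s.

    distance(p1, p2) x pixel_pitch / |t2 - t1|, sign discarded.  Each
    endpoint's activation time is read as the mean over a short pixel
    segment (half-width ``endpoint_halfwidth``) centered on the point
    along the probe axis: frame-rate quantization leaves a periodic
    sub-frame ripple on activation maps, and the symmetric segment
    average cancels it without biasing a locally linear wavefront
    (pass 0 to read the bare pixels).  Raises if either endpoint is
    invalid in the map or the activation times are closer than 0.5 ms
    (simultaneous activation gives an unbounded velocity).  With
    ``full=True`` returns a :class:`CVMeasurement` recording both
    activation times and the distance.
    """
    (r1, c1), (r2, c2) = probe.p1, probe.p2
    t1 = _endpoint_time(act_map.values, probe.p1, probe.p2, probe.p1,
                        endpoint_halfwidth)
    t2 = _endpoint_time(act_map.values, probe.p1, probe.p2, probe.p2,
                        endpoint_halfwidth)
    if not (np.isfinite(t1) and np.isfinite(t2)):
        raise ValueError("probe pixels must be valid in the activation map")
    dt = abs(t2 - t1)
    if dt < MIN_DELTA_T_MS:
        raise ValueError("points too close in time for a stable velocity "
                         f"(|dt| = {dt:.3f} ms < {MIN_DELTA_T_MS} ms)")
    dist_mm = float(np.hypot(r2 - r1, c2 - c1)) * probe.pixel_pitch
    cv = dist_mm / dt * 100.0  # mm/ms -> cm/s
    if full:
        return CVMeasurement(cv_cm_s=cv, t1_ms=t1, t2_ms=t2,
                             distance_mm=dist_mm, probe=probe)
    return cv


def _endpoint_time(values: np.ndarray, p1, p2, center,
                   halfwidth: int) -> float:
    """Mean activation over a (2*halfwidth + 1)-pixel segment through
    ``center`` along the p1->p2 axis; NaN if the center pixel is invalid."""
    r0, c0 = center
    if not np.isfinite(values[r0, c0]):
        return float("nan")
    if halfwidth <= 0:
        return float(values[r0, c0])
    dr, dc = p2[0] - p1[0], p2[1] - p1[1]
    norm = float(np.hypot(dr, dc))
    ur, uc = dr / norm, dc / norm
    rows, cols = values.shape
    samples = []
    for s in range(-halfwidth, halfwidth + 1):
        ri = int(round(r0 + ur * s))
        ci = int(round(c0 + uc * s))
        if 0 <= ri < rows and 0 <= ci < cols and np.isfinite(values[ri, ci]):
            samples.append(float(values[ri, ci]))
    return float(np.mean(samples)) if samples else float("nan")


def auto_probe(act_map: ActivationMap,
               roi: tuple[int, int, int, int] | None = None,
               smooth_sigma: float = 2.0) -> VectorProbe:
    """Place the measurement vector on the mean propagation axis.

    The activation-time gradient is computed on a smoothed copy of the
    map over the ROI; its mean unit direction defines the axis, and the
    probe points are placed on that axis through the ROI center,
    spanning at least 60 % of the ROI extent (snapped to the nearest
    valid pixels).  Raises when fewer than half the ROI pixels are
    valid or the gradient field is directionally incoherent (circular
    variance > 0.5) — e.g. a centered point source — in which case a
    manual probe is advised.
    """
    if roi is None:
        roi = default_roi(act_map.values.shape)
    r0, c0, r1, c1 = roi
    patch = act_map.values[r0:r1, c0:c1]
    valid = np.isfinite(patch)
    if valid.mean() < 0.5:
        raise ValueError("fewer than 50% of ROI pixels valid; "
                         "cannot place probe automatically")

    filled = _fill_nan_nearest(patch)
    sm = gaussian_filter(filled, sigma=smooth_sigma, mode="nearest")
    gy, gx = np.gradient(sm)
    mag = np.hypot(gy, gx)
    ok = valid & (mag > 1e-9)
    if ok.sum() < 8:
        raise ValueError("gradient field too sparse for automatic probe")
    uy = (gy[ok] / mag[ok]).mean()
    ux = (gx[ok] / mag[ok]).mean()
    resultant = float(np.hypot(uy, ux))
    circ_var = 1.0 - resultant
    if circ_var > MAX_CIRCULAR_VARIANCE:
        raise ValueError(
            f"activation gradient directionally incoherent (circular "
            f"variance {circ_var:.2f} > {MAX_CIRCULAR_VARIANCE}); "
            "select the probe manually")
    dy, dx = uy / resultant, ux / resultant

    cy, cx = (r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0
    # half-length: longest step along the axis staying inside the ROI
    steps = []
    if abs(dy) > 1e-12:
        steps.append(min(cy - r0, r1 - 1 - cy) / abs(dy))
    if abs(dx) > 1e-12:
        steps.append(min(cx - c0, c1 - 1 - cx) / abs(dx))
    half = min(steps)
    extent = float(np.hypot(r1 - r0, c1 - c0))
    if 2 * half < MIN_PROBE_SPAN * min(r1 - r0, c1 - c0):
        half = MIN_PROBE_SPAN * min(r1 - r0, c1 - c0) / 2.0
    p1 = _snap_valid(act_map.values, cy - dy * half, cx - dx * half, roi)
    p2 = _snap_valid(act_map.values, cy + dy * half, cx + dx * half, roi)
    if p1 == p2:
        raise ValueError("automatic probe degenerated to a single pixel")
    return VectorProbe(p1=p1, p2=p2, pixel_pitch=act_map.pixel_pitch,
                       selection_mode="auto")


def _fill_nan_nearest(a: np.ndarray) -> np.ndarray:
    """Replace NaNs with the nearest finite value (for smoothing only)."""
    if np.all(np.isfinite(a)):
        return a
    from scipy.ndimage import distance_transform_edt
    mask = ~np.isfinite(a)
    idx = distance_transform_edt(mask, return_distances=False,
                                 return_indices=True)
    return a[tuple(idx)]


def _snap_valid(values: np.ndarray, r: float, c: float,
                roi: tuple[int, int, int, int]) -> tuple[int, int]:
    """Nearest valid pixel to (r, c) inside the ROI."""
    r0, c0, r1, c1 = roi
    ri = int(np.clip(round(r), r0, r1 - 1))
    ci = int(np.clip(round(c), c0, c1 - 1))
    if np.isfinite(values[ri, ci]):
        return ri, ci
    rr, cc = np.mgrid[r0:r1, c0:c1]
    ok = np.isfinite(values[r0:r1, c0:c1])
    if not ok.any():
        raise ValueError("no valid pixels in ROI")
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    d2[~ok] = np.inf
    k = np.unravel_index(np.argmin(d2), d2.shape)
    return int(rr[k]), int(cc[k])


@dataclass
class IsochroneSet:
    """Contours of equal activation time at a fixed interval."""

    levels: list[float]
    contours: list[list[np.ndarray]]  # per level, list of (N, 2) rc paths
    interval: float
    cl: float

    @property
    def n_contours(self) -> int:
        return sum(len(c) for c in self.contours)

    def render(self, path, act_map: ActivationMap | None = None,
               probe: VectorProbe | None = None) -> None:
        """Write a PNG: activation-time colormap, isochrone lines, and
        the CV probe if given."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.2))
        if act_map is not None:
            im = ax.imshow(act_map.values, cmap="turbo", origin="upper")
            fig.colorbar(im, ax=ax, label="activation time (ms)")
        for level, paths in zip(self.levels, self.contours):
            for p in paths:
                ax.plot(p[:, 1], p[:, 0], color="k", lw=0.7)
        if probe is not None:
            (r1, c1), (r2, c2) = probe.p1, probe.p2
            ax.plot([c1, c2], [r1, r2], "w-o", ms=3, lw=1.2)
        ax.set_title(f"isochrones every {self.interval:g} ms "
                     f"(CL {self.cl:g} ms)")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def isochrone_map(act_map: ActivationMap, interval: float = 2.0
                  ) -> IsochroneSet:
    """Contour lines at multiples of ``interval`` ms over the valid region
    of an activation map.  All-equal activation times yield an empty
    contour set with a warning."""
    if interval <= 0:
        raise ValueError("interval must be > 0")
    vals = act_map.values
    finite = vals[np.isfinite(vals)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise ValueError("activation map needs >= 2 distinct valid times")
    lo, hi = float(finite.min()), float(finite.max())
    first = np.ceil(lo / interval) * interval
    levels = [float(v) for v in np.arange(first, hi, interval)]
    if not levels:
        warnings.warn("isochrone interval exceeds the activation span; "
                      "no contours drawn")
    contours = [measure.find_contours(vals, level) for level in levels]
    if hi - lo <= interval and len(levels) <= 1:
        warnings.warn("activation span smaller than the isochrone interval")
    return IsochroneSet(levels=levels, contours=contours,
                        interval=float(interval), cl=act_map.cl)
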