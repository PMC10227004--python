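"""Movie/metadata I/O, run configuration, and pipeline orchestration.

Movies are exchanged as multi-page 16-bit TIFF stacks (one page per
frame) with a JSON sidecar carrying acquisition metadata
(frame_interval_ms, pixel_pitch_mm, polarity, stimulus_times_ms,
cycle_lengths_ms, and the intensity scaling needed to undo the 16-bit
quantization).  Results are written as CSV tables, CSV/PNG maps, and a
machine-readable JSON statistics bundle under one run directory with a
manifest.

Coordinates are 0-based (row, col); ROI rectangles are half-open;
time is ms from the first frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tissue_sim import GroundTruth, PacingProtocol, VoltageMovie
from .preprocess import (SNR_FILTER_THRESHOLD, DEFAULT_SPATIAL_SIGMA,
                         DEFAULT_TEMPORAL_WINDOW, filter_movie,
                         normalize_movie, segment_beats)
from .activation_repol import (APD_MIN_CL_MS, build_maps, default_roi,
                               roi_stats)
from .conduction import VectorProbe, auto_probe, isochrone_map, single_vector_cv
from .restitution_stats import GroupTable, build_restitution, restitution_slope

logger = logging.getLogger("voltmap")

SIDECAR_REQUIRED_KEYS = ("frame_interval_ms", "pixel_pitch_mm", "polarity",
                         "stimulus_times_ms", "cycle_lengths_ms")


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    ``roi`` is a half-open (row0, col0, row1, col1) rectangle in pixel
    coordinates; ``None`` selects the default centered rectangle
    covering ~1/3 of the field.  APD is analyzed only at CLs >=
    ``apd_min_cl_ms`` (short CLs fuse beats); CV at every CL.
    """

    movie_path: str = ""
    out_dir: str = "voltmap_out"
    roi: tuple[int, int, int, int] | None = None
    cv_cls: list[float] | None = None    # None = all CLs in the movie
    apd_cls: list[float] | None = None   # None = all CLs >= apd_min_cl_ms
    apd_min_cl_ms: float = APD_MIN_CL_MS
    spatial_sigma: float = DEFAULT_SPATIAL_SIGMA
    temporal_window: int = DEFAULT_TEMPORAL_WINDOW
    snr_filter_threshold: float = SNR_FILTER_THRESHOLD
    isochrone_interval_ms: float = 2.0
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "roi" in data and data["roi"] is not None:
            data["roi"] = tuple(data["roi"])
        return cls(**data)

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


# --------------------------------------------------------------------------
# Movie read/write
# --------------------------------------------------------------------------

def write_movie(movie: VoltageMovie, directory, stem: str = "movie",
                truth: GroundTruth | None = None) -> Path:
    """Write a movie as ``<stem>.tif`` (multi-page 16-bit) plus
    ``<stem>.json`` sidecar; optional ground truth as per-beat CSVs.
    Returns the TIFF path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif_path = directory / f"{stem}.tif"

    frames = movie.frames
    lo = float(frames.min())
    hi = float(frames.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    quant = np.round((frames - lo) / scale).astype(np.uint16)
    tifffile.imwrite(tif_path, quant, photometric="minisblack")

    meta = {
        "frame_interval_ms": movie.frame_interval,
        "pixel_pitch_mm": movie.pixel_pitch,
        "polarity": movie.polarity,
        "stimulus_times_ms": list(map(float, movie.stimulus_times)),
        "cycle_lengths_ms": (list(map(float, movie.protocol.cycle_lengths))
                             if movie.protocol else
                             sorted({float(c) for c in movie.stimulus_cls},
                                    reverse=True)),
        "stimulus_cls_ms": list(map(float, movie.stimulus_cls)),
        "n_frames": int(movie.n_frames),
        "intensity_offset": lo,
        "intensity_scale": scale,
    }
    if movie.protocol is not None:
        meta["beats_per_cl"] = movie.protocol.beats_per_cl
        meta["stimulus_duration_ms"] = movie.protocol.stimulus_duration
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(meta, fh, indent=2)

    if truth is not None:
        write_ground_truth(truth, directory, stem)
    logger.info("movie written: %s (%d frames)", tif_path, movie.n_frames)
    return tif_path


def write_ground_truth(truth: GroundTruth, directory, stem: str = "movie"
                       ) -> None:
    """Per-beat ground-truth activation/APD fields as CSV grids."""
    directory = Path(directory)
    for b in truth.beats:
        tag = f"{stem}_truth_cl{int(b.cl)}_beat{b.beat_index}"
        np.savetxt(directory / f"{tag}_activation.csv", b.activation,
                   delimiter=",", fmt="%.4f")
        np.savetxt(directory / f"{tag}_apd80.csv", b.apd80,
                   delimiter=",", fmt="%.4f")


def read_movie(tif_path, sidecar_path=None) -> VoltageMovie:
    """Read a TIFF stack + JSON sidecar back into a :class:`VoltageMovie`.

    The sidecar (default: same stem, ``.json``) must carry every key in
    ``SIDECAR_REQUIRED_KEYS``; missing keys and frame-count mismatches
    are reported by name.
    """
    tif_path = Path(tif_path)
    if sidecar_path is None:
        sidecar_path = tif_path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"sidecar metadata {sidecar_path} not found; required keys: "
            f"{', '.join(SIDECAR_REQUIRED_KEYS)}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    missing = [k for k in SIDECAR_REQUIRED_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar missing required keys: {missing}")

    raw = tifffile.imread(tif_path)
    if raw.ndim == 2:
        raw = raw[None]
    if "n_frames" in meta and int(meta["n_frames"]) != raw.shape[0]:
        raise ValueError(f"frame count mismatch: TIFF has {raw.shape[0]} "
                         f"frames, sidecar says {meta['n_frames']}")
    offset = float(meta.get("intensity_offset", 0.0))
    scale = float(meta.get("intensity_scale", 1.0))
    frames = raw.astype(np.float64) * scale + offset

    protocol = None
    if "beats_per_cl" in meta:
        protocol = PacingProtocol(
            cycle_lengths=tuple(meta["cycle_lengths_ms"]),
            beats_per_cl=int(meta["beats_per_cl"]),
            stimulus_duration=float(meta.get("stimulus_duration_ms", 3.0)),
            start_time=float(meta["stimulus_times_ms"][0]))
    movie = VoltageMovie(
        frames=frames,
        frame_interval=float(meta["frame_interval_ms"]),
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        polarity=str(meta["polarity"]),
        protocol=protocol,
        stimulus_times=list(map(float, meta["stimulus_times_ms"])),
        stimulus_cls=list(map(float, meta.get("stimulus_cls_ms", []))))
    logger.info("movie loaded: %s (%d frames, %.0f ms)", tif_path,
                movie.n_frames, movie.duration)
    return movie


# --------------------------------------------------------------------------
# Pipeline orchestration
# --------------------------------------------------------------------------

@dataclass
class MovieResult:
    """Per-CL measurements for one movie/subject."""

    cv_by_cl: dict[float, float]
    apd_by_cl: dict[float, float]            # ROI mean APD80
    apd_sd_by_cl: dict[float, float]
    maps: dict                               # cl -> (ActivationMap, APDMap)
    probes: dict[float, VectorProbe]
    restitution: object | None = None        # RestitutionCurve when >= 2 CLs
    max_restitution_slope: float = float("nan")
    n_masked_pixels: int = 0
    filtered: bool = False

    def as_records(self, subject_id: str = "s0", group: str = "") -> list[dict]:
        """Tidy per-CL rows (subject_id, group, cl_ms, cv_cm_s, apd80_ms)."""
        cls = sorted(set(self.cv_by_cl) | set(self.apd_by_cl), reverse=True)
        return [{"subject_id": subject_id, "group": group, "cl_ms": cl,
                 "cv_cm_s": self.cv_by_cl.get(cl, np.nan),
                 "apd80_ms": self.apd_by_cl.get(cl, np.nan)}
                for cl in cls]


def analyze_movie(movie: VoltageMovie, config: RunConfig | None = None
                  ) -> MovieResult:
    """Run the full measurement chain on one movie.

    Normalize (polarity + per-pixel rescale) -> smooth if the median
    pixel SNR is below the filter threshold -> segment beats ->
    beat-averaged activation/APD80 maps per CL -> auto-probe
    single-vector CV -> ROI APD80 summary -> restitution curve and
    maximum segmentwise slope (when >= 2 APD CLs are available).
    """
    config = config or RunConfig()
    norm, mask = normalize_movie(movie)
    snr = mask.snr[np.isfinite(mask.snr)]
    med_snr = float(np.median(snr)) if snr.size else float("inf")
    filtered = med_snr < config.snr_filter_threshold
    if filtered:
        logger.info("median pixel SNR %.1f < %.1f: applying default "
                    "smoothing (sigma=%g px, window=%d frames)", med_snr,
                    config.snr_filter_threshold, config.spatial_sigma,
                    config.temporal_window)
        norm = filter_movie(norm, config.spatial_sigma, config.temporal_window)
    logger.info("masked pixels: %d / %d", mask.n_masked, mask.valid.size)

    windows = segment_beats(norm)
    logger.info("beats found: %d stimuli over %d cycle lengths",
                len(windows), len({w.cl for w in windows}))
    roi = config.roi or default_roi(norm.shape)
    maps = build_maps(norm, windows, mask=mask, roi=roi,
                      apd_min_cl=config.apd_min_cl_ms)

    cv_by_cl: dict[float, float] = {}
    apd_by_cl: dict[float, float] = {}
    apd_sd_by_cl: dict[float, float] = {}
    probes: dict[float, VectorProbe] = {}
    for cl, (amap, pmap) in maps.items():
        if config.cv_cls is None or cl in config.cv_cls:
            try:
                probe = auto_probe(amap, roi=roi)
                cv_by_cl[cl] = single_vector_cv(amap, probe)
                probes[cl] = probe
            except ValueError as exc:
                logger.warning("CV at CL %g ms not measurable: %s", cl, exc)
        if config.apd_cls is None or cl in config.apd_cls:
            mean, sd, n = roi_stats(pmap.values, roi)
            if n > 0:
                apd_by_cl[cl] = mean
                apd_sd_by_cl[cl] = sd
    logger.info("maps computed: CV at %d CLs, APD at %d CLs",
                len(cv_by_cl), len(apd_by_cl))

    restitution = None
    max_slope = float("nan")
    if len(apd_by_cl) >= 2:
        restitution = build_restitution(apd_by_cl)
        max_slope = restitution_slope(restitution, method="segmentwise")

    return MovieResult(cv_by_cl=cv_by_cl, apd_by_cl=apd_by_cl,
                       apd_sd_by_cl=apd_sd_by_cl, maps=maps, probes=probes,
                       restitution=restitution,
                       max_restitution_slope=max_slope,
                       n_masked_pixels=mask.n_masked, filtered=filtered)


def analyze_cohort(movies: list, config: RunConfig | None = None,
                   group: str = "") -> pd.DataFrame:
    """Analyze ``[(subject_id, movie, _), ...]`` into a tidy per-subject,
    per-CL measurement table (subject_id, group, cl_ms, cv_cm_s,
    apd80_ms) — the input layout of :func:`summarize_groups`."""
    rows = []
    for item in movies:
        sid, movie = item[0], item[1]
        res = analyze_movie(movie, config)
        rows.extend(res.as_records(subject_id=sid, group=group or
                                   sid.rsplit("_", 1)[0]))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Results output
# --------------------------------------------------------------------------

def write_results(out_dir, tables: dict[str, GroupTable] | None = None,
                  results: dict[str, MovieResult] | None = None,
                  config: RunConfig | None = None) -> Path:
    """Write group tables, per-subject measurements, maps, isochrones and
    a JSON statistics bundle under one run directory with a manifest.

    ``tables`` maps a measure name (e.g. ``"cv_cm_s"``) to its
    :class:`GroupTable`; ``results`` maps subject ids to per-movie
    results.  Empty inputs produce headers-only CSVs and still succeed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    stats_bundle: dict = {}

    tables = tables or {}
    for measure, table in tables.items():
        path = out_dir / f"table_{measure}.csv"
        df = table.summary.copy()
        trend_row: dict = {"cl_ms": "p_for_trend"}
        for g, (sign, p) in table.trend.items():
            trend_row[f"{g}_mean"] = p
        df = pd.concat([df, pd.DataFrame([trend_row])], ignore_index=True)
        df.to_csv(path, index=False)
        manifest.append(path.name)
        stats_bundle[measure] = {
            "summary": table.summary.to_dict(orient="records"),
            "pairwise_unadjusted": {str(cl): m.to_dict()
                                    for cl, m in table.pairwise.items()},
            "pairwise_holm": {str(cl): m.to_dict()
                              for cl, m in table.pairwise_adjusted.items()},
            "trend": {g: {"slope_sign": s, "p": p}
                      for g, (s, p) in table.trend.items()},
        }
    if not tables:
        path = out_dir / "table_empty.csv"
        pd.DataFrame(columns=["cl_ms", "mean", "sd", "n", "p_value"]
                     ).to_csv(path, index=False)
        manifest.append(path.name)

    results = results or {}
    rows = []
    for sid, res in results.items():
        rows.extend(res.as_records(subject_id=sid))
        for cl, (amap, pmap) in res.maps.items():
            tag = f"{sid}_cl{int(cl)}"
            np.savetxt(out_dir / f"{tag}_activation.csv", amap.values,
                       delimiter=",", fmt="%.4f")
            manifest.append(f"{tag}_activation.csv")
            if np.isfinite(pmap.values).any():
                np.savetxt(out_dir / f"{tag}_apd80.csv", pmap.values,
                           delimiter=",", fmt="%.4f")
                manifest.append(f"{tag}_apd80.csv")
            try:
                iso = isochrone_map(amap, interval=2.0)
                png = out_dir / f"{tag}_isochrones.png"
                iso.render(png, act_map=amap, probe=res.probes.get(cl))
                manifest.append(png.name)
            except ValueError:
                pass
    if rows:
        per_subject = out_dir / "measurements.csv"
        pd.DataFrame(rows).to_csv(per_subject, index=False)
        manifest.append(per_subject.name)

    if config is not None:
        config.to_json(out_dir / "config.json")
        manifest.append("config.json")

    stats_path = out_dir / "stats.json"
    with open(stats_path, "w") as fh:
        json.dump(stats_bundle, fh, indent=2, default=_json_default)
    manifest.append(stats_path.name)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"files": sorted(manifest)}, fh, indent=2)
    logger.info("results written under %s (%d files)", out_dir, len(manifest))
    return out_dir


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
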