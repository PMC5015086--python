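"""End-to-end pipeline driver: frames in, trajectories and statistics out.

Stage order follows the processing chain: time-averaged background ->
enhancement -> 2D segmentation -> 2D tracking -> depth (focus metric) ->
3D post-processing -> behavior statistics.  Frames are visited in two
streaming passes (one to accumulate the background, one for everything
else); no stage holds the full recording in memory, which is what makes
multi-hour sessions at 100 fps processable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .behavior import (
    closest_distance_pdf,
    detect_rapid_vertical,
    ethogram,
    spatial_pdf,
)
from .config import PipelineConfig
from .frames import HologramFrame, read_frames
from .preprocess import StreamingBackground, auto_threshold, enhance, segment
from .synth import ArenaBox
from .focus import estimate_depth
from .track2d import (
    STATUS_SINGLE,
    Tracker2D,
    detect_occlusions,
    exclude_overlaps,
    filter_single_tracks,
    resolve_short_overlap,
)
from .track3d import TooFewSeedsError, interpolate_gaps, to_metric, velocity_correct

__all__ = ["run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline produced."""

    out_dir: Path
    tracks2d: list
    tracks3d: list
    single_tracks3d: list
    events: list
    report: dict


def _frame_iter(source, fps: float) -> Iterator[HologramFrame]:
    if isinstance(source, (str, Path)):
        yield from read_frames(source, fps=fps)
    else:
        yield from source


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    frames,
    out_dir: str | Path,
    arena: ArenaBox | None = None,
) -> PipelineResult:
    """Run the full chain and write per-stage artifacts.

    ``frames`` is a path (multi-page TIFF or frame directory) or a
    sequence of :class:`HologramFrame`.  Deterministic for a fixed config
    and seed: the run report includes checksums of every CSV artifact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))

    # pass 1: time-averaged background
    acc = StreamingBackground()
    for frame in _frame_iter(frames, config.fps):
        acc.update(frame)
    bg = acc.finalize()
    log.info("background averaged over %d frames", bg.n_frames_used)

    if arena is None:
        fov_y, fov_x = (
            bg.mean_frame.shape[0] * config.optics.pixel_pitch_m,
            bg.mean_frame.shape[1] * config.optics.pixel_pitch_m,
        )
        base = ArenaBox()
        arena = ArenaBox(
            size_m=(
                min(base.size_m[0], fov_x),
                min(base.size_m[1], fov_y),
                base.size_m[2],
            )
        )

    # pass 2: enhance -> segment -> link -> depth, streaming
    tracker = Tracker2D(
        max_link_px=config.tracking.max_link_px,
        patience=config.tracking.patience_frames,
    )
    z_by_track: dict[int, dict[int, float | None]] = {}
    prior_z: dict[int, float] = {}
    det_rows = []
    n_frames = 0
    n_detections = 0
    for frame in _frame_iter(frames, config.fps):
        n_frames += 1
        enhanced = enhance(frame, bg, smooth_window=config.smooth_window_px)
        # unsmoothed version for depth: the moving average helps
        # segmentation but averages away the fine fringes that carry z
        enhanced_sharp = enhance(frame, bg, smooth_window=1)
        if np.ptp(enhanced) <= 0:
            tracker.step(frame.index, [])
            continue
        try:
            thr = auto_threshold(enhanced)
        except ValueError:
            tracker.step(frame.index, [])
            continue
        dets = segment(
            enhanced,
            thr,
            opening_diameter_px=config.opening_diameter_px,
            min_area_px=config.min_area_px,
            frame_index=frame.index,
        )
        n_detections += len(dets)
        tracker.step(frame.index, dets)
        # depth per freshly linked detection, using the track's last depth
        # as the multi-pass prior
        for t in tracker.tracks():
            if frame.index in t.samples and frame.index not in z_by_track.get(
                t.track_id, {}
            ):
                det = t.samples[frame.index]
                curve = estimate_depth(
                    enhanced_sharp,
                    det.centroid_px,
                    config.focus,
                    config.optics,
                    prior_z_m=prior_z.get(t.track_id),
                )
                z_by_track.setdefault(t.track_id, {})[frame.index] = (
                    curve.selected_z_m
                )
                if curve.selected_z_m is not None:
                    prior_z[t.track_id] = curve.selected_z_m
                det_rows.append(
                    {
                        "frame": frame.index,
                        "track_id": t.track_id,
                        "row_px": det.centroid_px[0],
                        "col_px": det.centroid_px[1],
                        "area_px": det.area_px,
                        "z_raw_mm": (
                            np.nan
                            if curve.selected_z_m is None
                            else curve.selected_z_m * 1e3
                        ),
                    }
                )

    tracks2d = tracker.tracks()
    pd.DataFrame(
        det_rows,
        columns=["frame", "track_id", "row_px", "col_px", "area_px", "z_raw_mm"],
    ).to_csv(out_dir / "detections.csv", index=False)

    # occlusion screening and short-overlap resolution
    detect_occlusions(
        tracks2d,
        area_jump_frac=config.tracking.area_jump_frac,
        proximity_px=config.tracking.proximity_px,
    )
    exclude_overlaps(tracks2d, max_objects=2)
    overlap_pairs = _overlapping_pairs(tracks2d)
    resolutions = {}
    for a, b in overlap_pairs:
        resolutions[(a.track_id, b.track_id)] = resolve_short_overlap(
            a, b, max_gap_frames=config.max_gap_frames
        )

    rows = []
    for t in tracks2d:
        for f in t.frames:
            d = t.samples[f]
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": f,
                    "row_px": d.centroid_px[0],
                    "col_px": d.centroid_px[1],
                    "area_px": d.area_px,
                    "status": t.status[f],
                }
            )
    pd.DataFrame(
        rows, columns=["track_id", "frame", "row_px", "col_px", "area_px", "status"]
    ).to_csv(out_dir / "tracks2d.csv", index=False)

    single2d = filter_single_tracks(
        tracks2d, min_length_frames=config.tracking.min_track_frames
    )
    single_ids = {t.track_id for t in single2d}

    # 3D post-processing
    tracks3d = []
    single3d = []
    dropped = []
    gap_frames = 0
    for t in tracks2d:
        if t.n_frames < 2:
            continue
        track3 = to_metric(
            t, z_by_track.get(t.track_id, {}), config.optics, fps=config.fps
        )
        gap_frames += int(np.isnan(track3.z_m).sum())
        try:
            track3 = interpolate_gaps(track3)
        except TooFewSeedsError as exc:
            dropped.append({"track_id": t.track_id, "reason": str(exc)})
            log.info("dropped track %d: %s", t.track_id, exc)
            continue
        track3 = velocity_correct(track3)
        tracks3d.append(track3)
        if t.track_id in single_ids:
            single3d.append(track3)

    if tracks3d:
        pd.concat([t.to_dataframe() for t in tracks3d]).to_csv(
            out_dir / "tracks3d.csv", index=False
        )
    else:
        pd.DataFrame(
            columns=["track_id", "frame", "t_s", "x_mm", "y_mm", "z_mm", "source"]
        ).to_csv(out_dir / "tracks3d.csv", index=False)

    # behavior statistics, single-fly tracks only by construction
    events = []
    etho_rows = []
    if single3d:
        pdf, edges = spatial_pdf(
            single3d, arena, bin_mm=config.behavior.spatial_bin_mm
        )
        np.savez_compressed(
            out_dir / "spatial_pdf.npz",
            pdf=pdf,
            x_edges_m=edges[0],
            y_edges_m=edges[1],
            z_edges_m=edges[2],
        )
        per_frame: dict[int, list] = {}
        for t in single3d:
            for i, f in enumerate(t.frames):
                per_frame.setdefault(int(f), []).append(
                    [t.x_m[i], t.y_m[i], t.z_m[i]]
                )
        dist_pdf = closest_distance_pdf(
            {f: np.array(p) for f, p in per_frame.items()},
            bin_mm=config.behavior.distance_bin_mm,
        )
        dist_pdf.to_csv(out_dir / "distance_pdf.csv", index=False)
        for t in single3d:
            states = ethogram(t, config.behavior.ethogram)
            etho_rows.extend(
                {"track_id": t.track_id, "frame": int(f), "state": s}
                for f, s in zip(t.frames, states)
            )
        events = detect_rapid_vertical(
            single3d,
            vz_thresh_mm_s=config.behavior.vz_thresh_mm_s,
            min_frames=config.behavior.event_min_frames,
            vertical_axis=config.behavior.vertical_axis,
        )
    pd.DataFrame(etho_rows, columns=["track_id", "frame", "state"]).to_csv(
        out_dir / "ethograms.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "track_id": e.track_id,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "peak_speed_mm_s": e.peak_speed_mm_s,
                "kind": e.kind,
            }
            for e in events
        ],
        columns=["track_id", "start_frame", "end_frame", "peak_speed_mm_s", "kind"],
    ).to_csv(out_dir / "events.csv", index=False)

    csvs = sorted(out_dir.glob("*.csv"))
    report = {
        "seed": config.seed,
        "n_frames": n_frames,
        "n_detections": n_detections,
        "n_tracks": len(tracks2d),
        "n_single_tracks": len(single2d),
        "single_track_fraction": (
            len(single2d) / len(tracks2d) if tracks2d else 0.0
        ),
        "n_tracks3d": len(tracks3d),
        "n_depth_gaps": gap_frames,
        "dropped_tracks": dropped,
        "overlap_resolutions": {
            f"{a}-{b}": r for (a, b), r in resolutions.items()
        },
        "n_events": len(events),
        "config": dataclasses.asdict(config),
        "checksums": {p.name: _md5(p) for p in csvs},
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return PipelineResult(
        out_dir=out_dir,
        tracks2d=tracks2d,
        tracks3d=tracks3d,
        single_tracks3d=single3d,
        events=events,
        report=report,
    )


def _overlapping_pairs(tracks):
    """Pairs of tracks sharing at least one overlap-flagged frame."""
    from .track2d import STATUS_OVERLAP

    flagged = {
        t.track_id: {f for f in t.frames if t.status.get(f) == STATUS_OVERLAP}
        for t in tracks
    }
    pairs = []
    for a, b in itertools.combinations(tracks, 2):
        fa, fb = flagged[a.track_id], flagged[b.track_id]
        if fa and fb and (fa & fb):
            pairs.append((a, b))
    return pairs
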