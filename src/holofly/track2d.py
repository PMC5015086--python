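"""Frame-to-frame association of 2D detections and occlusion screening.

Association minimizes total Euclidean position change between predicted
track positions and detections (nearest-neighbor cost, solved optimally
with the Hungarian algorithm), with a hard gate on link distance.  Because
a single camera projects the arena along the optical axis, flies routinely
overlap; overlap onset is flagged from area jumps and proximity, short
two-fly overlaps are resolved by constant-velocity extrapolation across the
gap, and everything else is excluded from single-fly statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .preprocess import Detection2D

__all__ = [
    "Track2D",
    "Tracker2D",
    "assign",
    "link_detections",
    "detect_occlusions",
    "resolve_short_overlap",
    "filter_single_tracks",
]

log = logging.getLogger(__name__)

STATUS_SINGLE = "single"
STATUS_OVERLAP = "overlap-candidate"
STATUS_EXCLUDED = "excluded"

_GATE_COST = 1e12


@dataclass
class Track2D:
    """A time-linked sequence of 2D detections for one object."""

    track_id: int
    samples: dict[int, Detection2D] = field(default_factory=dict)
    status: dict[int, str] = field(default_factory=dict)
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def add(self, det: Detection2D, status: str = STATUS_SINGLE) -> None:
        if det.frame_index in self.samples:
            raise ValueError(
                f"track {self.track_id} already has frame {det.frame_index}"
            )
        if self.samples and det.frame_index <= max(self.samples):
            raise ValueError("frames must be added in increasing order")
        self.samples[det.frame_index] = det
        self.status[det.frame_index] = status

    @property
    def frames(self) -> list[int]:
        return sorted(self.samples)

    @property
    def n_frames(self) -> int:
        return len(self.samples)

    def position(self, frame: int) -> np.ndarray:
        return np.asarray(self.samples[frame].centroid_px, dtype=float)

    def predict(self, frame: int) -> np.ndarray:
        """Constant-velocity prediction from the last two samples.

        Falls back to the last observed position for single-sample tracks.
        """
        fs = self.frames
        last = fs[-1]
        p_last = self.position(last)
        if len(fs) < 2:
            return p_last
        prev = fs[-2]
        v = (p_last - self.position(prev)) / (last - prev)
        return p_last + v * (frame - last)


@dataclass
class AssignmentResult:
    matches: list[tuple[int, int]]  # (track list index, detection index)
    unmatched_tracks: list[int]
    unmatched_detections: list[int]


def assign(
    tracks: list[Track2D],
    detections: list[Detection2D],
    max_link_px: float,
    frame: int | None = None,
) -> AssignmentResult:
    """Optimal minimum-total-distance assignment with gating.

    Costs are Euclidean distances between each track's predicted position
    (at ``frame``, or one past its last sample) and each detection's
    centroid; pairs farther apart than ``max_link_px`` are forbidden.
    """
    if not tracks or not detections:
        return AssignmentResult(
            [], list(range(len(tracks))), list(range(len(detections)))
        )
    preds = np.stack(
        [
            t.predict(frame if frame is not None else t.frames[-1] + 1)
            for t in tracks
        ]
    )
    lasts = np.stack([t.position(t.frames[-1]) for t in tracks])
    cents = np.stack([np.asarray(d.centroid_px, float) for d in detections])
    cost = np.linalg.norm(preds[:, None, :] - cents[None, :, :], axis=2)
    # gate on both the prediction and the last observed position, so a
    # track can never contain a jump larger than the link radius
    jump = np.linalg.norm(lasts[:, None, :] - cents[None, :, :], axis=2)
    gated = (cost > max_link_px) | (jump > max_link_px)
    cost = np.where(gated, _GATE_COST, cost)
    rows, cols = linear_sum_assignment(cost)
    matches = [
        (int(r), int(c)) for r, c in zip(rows, cols) if not gated[r, c]
    ]
    matched_t = {r for r, _ in matches}
    matched_d = {c for _, c in matches}
    return AssignmentResult(
        matches=matches,
        unmatched_tracks=[i for i in range(len(tracks)) if i not in matched_t],
        unmatched_detections=[
            j for j in range(len(detections)) if j not in matched_d
        ],
    )


class Tracker2D:
    """Streaming multi-object tracker.

    Feed detections frame by frame with :meth:`step`; finished and active
    tracks are available from :meth:`tracks`.  Tracks unmatched for more
    than ``patience`` consecutive frames are terminated.
    """

    def __init__(self, max_link_px: float = 200.0, patience: int = 5):
        self.max_link_px = max_link_px
        self.patience = patience
        self._active: list[Track2D] = []
        self._misses: dict[int, int] = {}
        self._finished: list[Track2D] = []
        self._next_id = 0

    def step(self, frame: int, detections: list[Detection2D]) -> None:
        res = assign(self._active, detections, self.max_link_px, frame=frame)
        for ti, di in res.matches:
            self._active[ti].add(detections[di])
            self._misses[self._active[ti].track_id] = 0
        for ti in res.unmatched_tracks:
            tid = self._active[ti].track_id
            self._misses[tid] = self._misses.get(tid, 0) + 1
        for di in res.unmatched_detections:
            t = Track2D(track_id=self._next_id)
            self._next_id += 1
            t.add(detections[di])
            self._active.append(t)
            self._misses[t.track_id] = 0
        still_active = []
        for t in self._active:
            if self._misses[t.track_id] > self.patience:
                self._finished.append(t)
            else:
                still_active.append(t)
        self._active = still_active

    def tracks(self) -> list[Track2D]:
        return sorted(
            self._finished + self._active, key=lambda t: t.track_id
        )


def link_detections(
    detections_by_frame: dict[int, list[Detection2D]],
    max_link_px: float = 200.0,
    patience: int = 5,
) -> list[Track2D]:
    """Link per-frame detections into tracks over a whole session."""
    tracker = Tracker2D(max_link_px=max_link_px, patience=patience)
    for frame in sorted(detections_by_frame):
        tracker.step(frame, detections_by_frame[frame])
    return tracker.tracks()


def _running_median(values: np.ndarray, window: int = 31) -> np.ndarray:
    """Median of up to ``window`` preceding samples (inclusive)."""
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo = max(0, i - window + 1)
        out[i] = np.median(values[lo : i + 1])
    return out


def detect_occlusions(
    tracks: list[Track2D],
    area_jump_frac: float = 0.5,
    proximity_px: float = 150.0,
) -> list[Track2D]:
    """Flag frames at risk of overlap; record contiguous spans as gaps.

    A frame is an overlap candidate when the track's area deviates from its
    running median by more than ``area_jump_frac`` (two flies merged into
    one blob roughly doubles the area) or when another track's centroid is
    within ``proximity_px``.  Statuses are updated in place.
    """
    positions: dict[int, list[tuple[int, np.ndarray]]] = {}
    for idx, t in enumerate(tracks):
        for f in t.frames:
            positions.setdefault(f, []).append((idx, t.position(f)))

    for idx, t in enumerate(tracks):
        fs = t.frames
        areas = np.array([t.samples[f].area_px for f in fs], dtype=float)
        med = _running_median(areas)
        flagged = []
        for k, f in enumerate(fs):
            jump = med[k] > 0 and abs(areas[k] - med[k]) / med[k] > area_jump_frac
            near = any(
                other != idx
                and np.linalg.norm(p - t.position(f)) <= proximity_px
                for other, p in positions.get(f, [])
            )
            if jump or near:
                t.status[f] = STATUS_OVERLAP
                flagged.append(f)
        t.gaps = _spans(flagged)
    return tracks


def _spans(frames: list[int]) -> list[tuple[int, int]]:
    """Contiguous (start, end) inclusive spans from a sorted frame list."""
    spans: list[tuple[int, int]] = []
    for f in frames:
        if spans and f == spans[-1][1] + 1:
            spans[-1] = (spans[-1][0], f)
        else:
            spans.append((f, f))
    return spans


def resolve_short_overlap(
    track_a: Track2D,
    track_b: Track2D,
    max_gap_frames: int,
    ambiguity_tol: float = 1e-6,
) -> str:
    """Re-identify two tracks after a short mutual overlap.

    Both tracks must have samples before and after a common overlap span
    (flagged frames and/or missing frames).  Post-overlap segments are
    assigned to pre-overlap identities by minimizing the total deviation
    from constant-velocity extrapolation across the gap; if that prefers
    the crossed pairing, the post-overlap samples are swapped in place.

    Returns ``"kept"``, ``"swapped"``, or ``"excluded"`` (overlap too long
    or the two pairings are indistinguishable); excluded frames are marked
    so single-fly statistics drop them.
    """
    span = _common_overlap_span(track_a, track_b)
    if span is None:
        return "kept"
    g0, g1 = span
    if g1 - g0 + 1 > max_gap_frames:
        _exclude_from(track_a, g0)
        _exclude_from(track_b, g0)
        log.info(
            "overlap of tracks %d/%d longer than %d frames: excluded",
            track_a.track_id, track_b.track_id, max_gap_frames,
        )
        return "excluded"

    cost_keep = _cross_gap_cost(track_a, track_a, g0, g1) + _cross_gap_cost(
        track_b, track_b, g0, g1
    )
    cost_swap = _cross_gap_cost(track_a, track_b, g0, g1) + _cross_gap_cost(
        track_b, track_a, g0, g1
    )
    if not np.isfinite(cost_keep) and not np.isfinite(cost_swap):
        _exclude_from(track_a, g0)
        _exclude_from(track_b, g0)
        return "excluded"
    if abs(cost_keep - cost_swap) <= ambiguity_tol:
        _exclude_from(track_a, g0)
        _exclude_from(track_b, g0)
        log.info(
            "ambiguous overlap of tracks %d/%d: excluded",
            track_a.track_id, track_b.track_id,
        )
        return "excluded"
    if cost_swap < cost_keep:
        _swap_after(track_a, track_b, g1)
        return "swapped"
    return "kept"


def exclude_overlaps(
    tracks: list[Track2D], max_objects: int = 2
) -> list[Track2D]:
    """Exclude overlap spans involving more than ``max_objects`` tracks."""
    by_frame: dict[int, list[Track2D]] = {}
    for t in tracks:
        for f in t.frames:
            if t.status.get(f) == STATUS_OVERLAP:
                by_frame.setdefault(f, []).append(t)
    for f, involved in by_frame.items():
        if len(involved) > max_objects:
            for t in involved:
                t.status[f] = STATUS_EXCLUDED
    return tracks


def _common_overlap_span(
    track_a: Track2D, track_b: Track2D
) -> tuple[int, int] | None:
    def bad_frames(t: Track2D) -> set[int]:
        fs = t.frames
        missing = set(range(fs[0], fs[-1] + 1)) - set(fs)
        flagged = {
            f for f in fs if t.status.get(f) in (STATUS_OVERLAP, STATUS_EXCLUDED)
        }
        return missing | flagged

    bad = bad_frames(track_a) | bad_frames(track_b)
    if not bad:
        return None
    return (min(bad), max(bad))


def _cross_gap_cost(pre: Track2D, post: Track2D, g0: int, g1: int) -> float:
    """Deviation of post-gap samples from pre-gap constant-velocity motion."""
    pre_frames = [f for f in pre.frames if f < g0]
    post_frames = [f for f in post.frames if f > g1][:5]
    if not pre_frames or not post_frames:
        return np.inf
    f1 = pre_frames[-1]
    p1 = pre.position(f1)
    if len(pre_frames) >= 2:
        f0 = pre_frames[-2]
        v = (p1 - pre.position(f0)) / (f1 - f0)
    else:
        v = np.zeros(2)
    return float(
        sum(
            np.linalg.norm(post.position(f) - (p1 + v * (f - f1)))
            for f in post_frames
        )
    )


def _exclude_from(track: Track2D, frame: int) -> None:
    for f in track.frames:
        if f >= frame:
            track.status[f] = STATUS_EXCLUDED


def _swap_after(track_a: Track2D, track_b: Track2D, g1: int) -> None:
    tail_a = {f: track_a.samples.pop(f) for f in track_a.frames if f > g1}
    stat_a = {f: track_a.status.pop(f) for f in list(track_a.status) if f > g1}
    tail_b = {f: track_b.samples.pop(f) for f in track_b.frames if f > g1}
    stat_b = {f: track_b.status.pop(f) for f in list(track_b.status) if f > g1}
    track_a.samples.update(tail_b)
    track_a.status.update(stat_b)
    track_b.samples.update(tail_a)
    track_b.status.update(stat_a)


def filter_single_tracks(
    tracks: list[Track2D], min_length_frames: int = 10
) -> list[Track2D]:
    """Tracks usable for single-fly statistics.

    Keeps tracks whose frames are all ``single`` and that are at least
    ``min_length_frames`` long; logs the retained fraction.
    """
    kept = [
        t
        for t in tracks
        if t.n_frames >= min_length_frames
        and all(s == STATUS_SINGLE for s in t.status.values())
    ]
    if tracks:
        log.info(
            "single-fly screening retained %d/%d tracks (%.0f%%)",
            len(kept), len(tracks), 100.0 * len(kept) / len(tracks),
        )
    return kept
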