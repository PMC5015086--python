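"""2D linking, occlusion flagging, overlap resolution, screening."""

import itertools

import numpy as np
import pytest

from holofly.preprocess import Detection2D
from holofly.track2d import (
    STATUS_EXCLUDED,
    STATUS_OVERLAP,
    STATUS_SINGLE,
    Track2D,
    assign,
    detect_occlusions,
    filter_single_tracks,
    link_detections,
    resolve_short_overlap,
)


def det(frame, row, col, area=800):
    half = 20
    return Detection2D(
        frame_index=frame,
        centroid_px=(row, col),
        area_px=area,
        bbox=(int(row) - half, int(col) - half, int(row) + half, int(col) + half),
    )


def track_from(points, track_id=0, areas=None, t0=0):
    t = Track2D(track_id=track_id)
    for k, (r, c) in enumerate(points):
        a = 800 if areas is None else areas[k]
        t.add(det(t0 + k, r, c, area=a))
    return t


def brute_force_assignment(track_pos, det_pos, max_link):
    """Exhaustive minimum-distance matching (gated), for <= 5 objects."""
    n_t, n_d = len(track_pos), len(det_pos)
    best_cost, best = np.inf, []
    k = min(n_t, n_d)
    # objective mirrors gated assignment: first maximize the number of
    # allowed links, then minimize their total distance
    for t_sub in itertools.permutations(range(n_t), k):
        for d_sub in itertools.combinations(range(n_d), k):
            pairs, cost = [], 0.0
            for ti, di in zip(t_sub, d_sub):
                d = np.linalg.norm(
                    np.array(track_pos[ti]) - np.array(det_pos[di])
                )
                if d > max_link:
                    continue
                pairs.append((ti, di))
                cost += d
            better = len(pairs) > len(best) or (
                len(pairs) == len(best) and cost < best_cost
            )
            if better:
                best_cost, best = cost, pairs
    return best_cost, best


class TestAssign:
    def test_exact_position_matches_at_zero_cost(self):
        t = track_from([(100.0, 100.0)])
        res = assign([t], [det(1, 100.0, 100.0)], max_link_px=50)
        assert res.matches == [(0, 0)]

    def test_distant_detection_not_linked(self):
        t = track_from([(0.0, 0.0)])
        res = assign([t], [det(1, 300.0, 400.0)], max_link_px=100)
        assert res.matches == []
        assert res.unmatched_tracks == [0]
        assert res.unmatched_detections == [0]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_optimum(self, seed):
        """Hungarian solution equals the exhaustive permutation minimum."""
        rng = np.random.default_rng(seed)
        n_t = rng.integers(1, 6)
        n_d = rng.integers(1, 6)
        track_pos = rng.uniform(0, 500, size=(n_t, 2))
        det_pos = rng.uniform(0, 500, size=(n_d, 2))
        tracks = [track_from([tuple(p)], track_id=i)
                  for i, p in enumerate(track_pos)]
        dets = [det(1, *p) for p in det_pos]
        res = assign(tracks, dets, max_link_px=400)
        cost = sum(
            np.linalg.norm(track_pos[ti] - det_pos[di])
            for ti, di in res.matches
        )
        bf_cost, bf = brute_force_assignment(track_pos, det_pos, 400)
        assert len(res.matches) == len(bf)
        assert cost == pytest.approx(bf_cost, abs=1e-9)

    def test_constant_velocity_prediction_beats_last_position(self):
        # fly moving +10 px/frame in col; detection continues the motion
        t = track_from([(100.0, 100.0), (100.0, 110.0)])
        decoy = det(2, 100.0, 108.0)
        continuation = det(2, 100.0, 120.0)
        res = assign([t], [decoy, continuation], max_link_px=50, frame=2)
        matched_det = [di for ti, di in res.matches if ti == 0][0]
        assert matched_det == 1


class TestLinking:
    def test_no_identity_switch_on_separated_flies(self):
        frames = {}
        for k in range(100):
            frames[k] = [
                det(k, 100.0 + 0.5 * k, 100.0),
                det(k, 400.0 - 0.5 * k, 400.0),
            ]
        tracks = link_detections(frames, max_link_px=100)
        assert len(tracks) == 2
        for t in tracks:
            cols = [t.position(f)[1] for f in t.frames]
            assert np.ptp(cols) < 1e-9  # each track stays in its column

    def test_track_terminated_after_patience(self):
        frames = {k: [det(k, 50.0, 50.0)] for k in range(5)}
        frames.update({k: [] for k in range(5, 15)})
        frames[15] = [det(15, 50.0, 50.0)]
        tracks = link_detections(frames, max_link_px=50, patience=3)
        assert len(tracks) == 2  # reappearance starts a fresh track

    def test_no_jump_exceeds_gate(self):
        rng = np.random.default_rng(4)
        frames = {
            k: [det(k, *rng.uniform(0, 500, 2)) for _ in range(3)]
            for k in range(30)
        }
        tracks = link_detections(frames, max_link_px=80)
        for t in tracks:
            fs = t.frames
            for a, b in zip(fs, fs[1:]):
                if b - a == 1:
                    jump = np.linalg.norm(t.position(b) - t.position(a))
                    assert jump <= 80 + 1e-9


class TestDetectOcclusions:
    def test_lone_constant_track_stays_single(self):
        t = track_from([(100.0, 100.0 + k) for k in range(20)])
        detect_occlusions([t], proximity_px=50)
        assert all(s == STATUS_SINGLE for s in t.status.values())

    def test_area_doubling_flagged_while_isolated(self):
        areas = [800] * 10 + [1700] * 3 + [800] * 10
        t = track_from([(100.0, 100.0) for _ in areas], areas=areas)
        detect_occlusions([t], area_jump_frac=0.5, proximity_px=10)
        flagged = [f for f, s in t.status.items() if s == STATUS_OVERLAP]
        assert set(flagged) == {10, 11, 12}
        assert t.gaps == [(10, 12)]

    def test_proximity_flags_both_tracks(self):
        a = track_from([(100.0, 100.0 + 10 * k) for k in range(10)], 0)
        b = track_from([(100.0, 190.0 - 10 * k) for k in range(10)], 1)
        detect_occlusions([a, b], proximity_px=30, area_jump_frac=5.0)
        # paths meet around col 145 at frame 4-5
        assert a.status[4] == STATUS_OVERLAP
        assert b.status[5] == STATUS_OVERLAP
        assert a.status[0] == STATUS_SINGLE


class TestResolveShortOverlap:
    def _crossing(self, swap_after_gap):
        """Two constant-velocity tracks with a 3-frame mutual gap."""
        va, vb = 10.0, -8.0
        a = Track2D(track_id=0)
        b = Track2D(track_id=1)
        for k in range(8):
            a.add(det(k, 100.0, 100.0 + va * k))
            b.add(det(k, 100.0, 180.0 + vb * k))
        # frames 8-10 missing (merged blob); resume at 11
        for k in range(11, 18):
            pa = (100.0, 100.0 + va * k)
            pb = (100.0, 180.0 + vb * k)
            if swap_after_gap:
                pa, pb = pb, pa
            a.add(det(k, *pa))
            b.add(det(k, *pb))
        return a, b

    def test_correct_continuation_kept(self):
        a, b = self._crossing(swap_after_gap=False)
        assert resolve_short_overlap(a, b, max_gap_frames=50) == "kept"

    def test_swapped_identities_repaired(self):
        a, b = self._crossing(swap_after_gap=True)
        assert resolve_short_overlap(a, b, max_gap_frames=50) == "swapped"
        frames = np.array(a.frames)
        cols_a = np.array([a.position(f)[1] for f in a.frames])
        velocity = np.diff(cols_a) / np.diff(frames)
        assert np.allclose(velocity, 10.0)  # track 0 moves at +10 again

    def test_long_overlap_excluded(self):
        a, b = self._crossing(swap_after_gap=False)
        assert resolve_short_overlap(a, b, max_gap_frames=2) == "excluded"
        assert all(
            a.status[f] == STATUS_EXCLUDED for f in a.frames if f >= 8
        )

    def test_ambiguous_costs_excluded(self):
        # both flies stationary at the same spot: pairings indistinguishable
        a = track_from([(100.0, 100.0)] * 5, 0)
        b = track_from([(100.0, 100.0)] * 5, 1)
        for k in range(7, 12):
            a.add(det(k, 100.0, 100.0))
            b.add(det(k, 100.0, 100.0))
        assert resolve_short_overlap(a, b, max_gap_frames=50) == "excluded"


class TestFilterSingleTracks:
    def test_clean_tracks_retained(self):
        tracks = [track_from([(10.0, 10.0 + k) for k in range(20)], i)
                  for i in range(3)]
        assert len(filter_single_tracks(tracks, min_length_frames=10)) == 3

    def test_flagged_or_short_tracks_dropped(self):
        good = track_from([(10.0, 10.0 + k) for k in range(20)], 0)
        short = track_from([(10.0, 10.0)] * 3, 1)
        flagged = track_from([(10.0, 10.0 + k) for k in range(20)], 2)
        flagged.status[5] = STATUS_OVERLAP
        kept = filter_single_tracks([good, short, flagged],
                                    min_length_frames=10)
        assert [t.track_id for t in kept] == [0]
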