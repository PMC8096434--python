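import math

import numpy as np
import pytest

from btx import synthetic_scene
from btx.segmentation import Blob, SegmentationConfig, estimate_background, segment_frame
from btx.tracking import (
    Assignment,
    Individual,
    MatchClique,
    Tracker,
    TrackerConfig,
    TreeComplexityExceeded,
    assignment_total,
    build_cliques,
    greedy_match,
    hungarian_match,
    match_probability,
    predict_state,
    split_overlapping,
    tree_match,
)


def point_blob(x, y):
    return Blob(ys=[int(y)], xs=[int(x)], values=[100])


def individual_with_path(points, dt=0.04, identity=0):
    ind = Individual(identity)
    for k, (x, y) in enumerate(points):
        ind.add(Assignment(frame=k, time=k * dt, x=x, y=y, probability=1.0), None)
    return ind


def brute_force_optimum(clique: MatchClique) -> float:
    """Exhaustive enumeration over all conflict-free partial assignments."""
    trajs = clique.trajectories

    def rec(k, used):
        if k == len(trajs):
            return 0.0
        best = rec(k + 1, used)  # leave unassigned
        for b in clique.blobs:
            if b in used:
                continue
            p = clique.edges.get((trajs[k], b))
            if p is not None:
                best = max(best, p + rec(k + 1, used | {b}))
        return best

    return rec(0, frozenset())


class TestPredictState:
    def test_stationary_history_predicts_last_position(self):
        ind = individual_with_path([(10, 20)] * 4)
        (px, py), _ = predict_state(ind, 4 * 0.04)
        assert (px, py) == (10, 20)

    def test_constant_velocity_extrapolates_linearly(self):
        ind = individual_with_path([(k * 2.0, 5.0) for k in range(5)])
        (px, py), _ = predict_state(ind, 5 * 0.04)
        assert px == pytest.approx(10.0, abs=1e-6)
        assert py == pytest.approx(5.0, abs=1e-6)

    def test_circular_motion_advances_heading_by_angular_step(self):
        omega = 0.3  # rad per frame
        dt = 0.04
        r = 30.0
        pts = [(50 + r * math.cos(omega * k), 50 + r * math.sin(omega * k))
               for k in range(8)]
        ind = individual_with_path(pts, dt=dt)
        _, heading = predict_state(ind, 8 * dt)
        # chord headings advance by omega each frame
        expect = math.atan2(pts[7][1] - pts[6][1], pts[7][0] - pts[6][0]) + omega
        assert heading == pytest.approx(expect, abs=0.05)

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            predict_state(Individual(0), 1.0)


class TestMatchProbability:
    CFG = TrackerConfig(track_max_speed=300.0)

    def test_perfect_prediction_scores_one(self):
        ind = individual_with_path([(10, 10)] * 3)
        p = match_probability(ind, point_blob(10, 10), 3 * 0.04, self.CFG, 0.04)
        # blob centroid is the pixel centre (10.5, 10.5): evaluate the kernel
        sigma = 300.0 * 0.04 / 3
        d = math.hypot(0.5, 0.5)
        assert p == pytest.approx(math.exp(-d * d / (2 * sigma * sigma)), rel=1e-9)

    def test_one_sigma_distance(self):
        ind = individual_with_path([(10.5, 10.5)] * 3)
        sigma = 300.0 * 0.04 / 3.0
        p = match_probability(ind, point_blob(10.5 + sigma - 0.5, 10), 3 * 0.04,
                              self.CFG, 0.04)
        assert p == pytest.approx(math.exp(-0.5), rel=1e-9)

    def test_zero_beyond_hard_radius(self):
        ind = individual_with_path([(10, 10)] * 3)
        radius = 300.0 * 0.04
        p = match_probability(ind, point_blob(10 + radius + 1, 10), 3 * 0.04,
                              self.CFG, 0.04)
        assert p == 0.0

    def test_gap_decay_halves_per_reassign_time(self):
        ind = individual_with_path([(10.0, 10.5)] * 3)
        t_gap = 3 * 0.04 + self.CFG.max_reassign_time  # one extra half-life
        p_now = match_probability(ind, point_blob(10, 10), 3 * 0.04, self.CFG, 0.04)
        p_late = match_probability(ind, point_blob(10, 10), t_gap, self.CFG, 0.04)
        # same zero distance, later arrival: decay close to 0.5 (kernel wider)
        assert p_late < p_now
        assert p_late / p_now == pytest.approx(0.5, abs=0.05)


class TestMatchers:
    def clique_from_matrix(self, p):
        edges = {(i, b): p[i][b] for i in range(len(p)) for b in range(len(p[0]))
                 if p[i][b] > 0}
        return MatchClique(trajectories=list(range(len(p))),
                           blobs=list(range(len(p[0]))), edges=edges)

    def test_single_edge(self):
        c = self.clique_from_matrix([[0.9]])
        assert tree_match(c) == {0: 0}
        assert hungarian_match(c) == {0: 0}

    def test_worked_two_by_two(self):
        c = self.clique_from_matrix([[0.9, 0.8], [0.85, 0.1]])
        for match in (tree_match(c), hungarian_match(c)):
            assert match == {0: 1, 1: 0}
            assert assignment_total(c, match) == pytest.approx(1.65)

    def test_greedy_is_suboptimal_on_worked_example(self):
        c = self.clique_from_matrix([[0.9, 0.8], [0.85, 0.1]])
        match = greedy_match(c, blob_order=[0, 1])
        assert assignment_total(c, match) == pytest.approx(1.0)

    def test_greedy_equals_optimum_without_conflicts(self):
        c = self.clique_from_matrix([[0.9, 0.0], [0.0, 0.8]])
        assert assignment_total(c, greedy_match(c)) == pytest.approx(1.7)

    def test_empty_clique(self):
        c = MatchClique(trajectories=[], blobs=[], edges={})
        assert tree_match(c) == {}
        assert greedy_match(c) == {}

    def test_all_equal_probabilities_deterministic(self):
        c = self.clique_from_matrix([[0.5] * 3] * 3)
        m1 = hungarian_match(c)
        m2 = hungarian_match(c)
        assert m1 == m2
        assert assignment_total(c, m1) == pytest.approx(1.5)

    def test_node_cap_raises_fallback_signal(self):
        n = 9
        p = [[0.5 + 0.001 * (i + j) for j in range(n)] for i in range(n)]
        c = self.clique_from_matrix(p)
        with pytest.raises(TreeComplexityExceeded):
            tree_match(c, node_cap=50)

    @pytest.mark.parametrize("trial", range(25))
    def test_matchers_agree_with_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        nt, nb = rng.integers(1, 6, 2)
        c = MatchClique(trajectories=list(range(nt)), blobs=list(range(nb)), edges={})
        for i in range(nt):
            for b in range(nb):
                if rng.random() < 0.7:
                    c.edges[(i, b)] = float(rng.uniform(0.05, 1.0))
        opt = brute_force_optimum(c)
        assert assignment_total(c, tree_match(c)) == pytest.approx(opt, abs=1e-9)
        assert assignment_total(c, hungarian_match(c)) == pytest.approx(opt, abs=1e-9)
        assert assignment_total(c, greedy_match(c)) <= opt + 1e-12


class TestBuildCliques:
    CFG = TrackerConfig(track_max_speed=300.0)

    def test_far_apart_pairs_form_singletons(self):
        inds = {0: individual_with_path([(10, 10)] * 3),
                1: individual_with_path([(200, 200)] * 3, identity=1)}
        blobs = [point_blob(10, 10), point_blob(200, 200)]
        cliques, ut, ub = build_cliques(inds, blobs, 3 * 0.04, self.CFG, 0.04)
        assert len(cliques) == 2
        assert all(len(c.trajectories) == 1 and len(c.blobs) == 1 for c in cliques)
        assert ut == [] and ub == []

    def test_chain_merges_into_one_clique(self):
        inds = {0: individual_with_path([(10, 10)] * 3),
                1: individual_with_path([(16, 10)] * 3, identity=1)}
        blobs = [point_blob(13, 10), point_blob(19, 10)]
        cliques, _, _ = build_cliques(inds, blobs, 3 * 0.04, self.CFG, 0.04)
        assert len(cliques) == 1
        assert cliques[0].trajectories == [0, 1]
        assert cliques[0].blobs == [0, 1]

    def test_no_edges_flags_everyone_unmatched(self):
        inds = {0: individual_with_path([(10, 10)] * 3)}
        blobs = [point_blob(300, 300)]
        cliques, ut, ub = build_cliques(inds, blobs, 3 * 0.04, self.CFG, 0.04)
        assert cliques == [] and ut == [0] and ub == [0]


def gradient_disc(img, cx, cy, r, center_darkness):
    """Radially shaded disc: darkest at centre, fading toward the rim."""
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    d = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy)
    inside = d <= r
    shade = center_darkness * (1.0 - 0.75 * (d / r) ** 2)
    img[inside] = np.clip(img[inside] - shade[inside], 0, 255)
    return inside


class TestSplitOverlapping:
    BG = np.full((60, 90), 200, np.uint8)

    def _blob(self, img):
        fg = np.abs(img.astype(int) - 200) >= 25
        ys, xs = np.nonzero(fg)
        return Blob(ys=ys, xs=xs, values=img[ys, xs])

    def test_two_shaded_discs_split_near_truth(self):
        img = self.BG.astype(float).copy()
        gradient_disc(img, 30, 30, 12, 150)
        gradient_disc(img, 52, 30, 12, 110)
        blob = self._blob(img.astype(np.uint8))
        pieces, ok = split_overlapping(blob, 2, self.BG, start_threshold=25)
        assert ok and len(pieces) == 2
        centers = sorted(p.centroid for p in pieces)
        assert abs(centers[0][0] - 30) < 2 and abs(centers[0][1] - 30) < 2
        assert abs(centers[1][0] - 52) < 2 and abs(centers[1][1] - 30) < 2
        # every original pixel re-attached to one of the pieces
        assert sum(p.n_pixels for p in pieces) == blob.n_pixels

    def test_uniform_blob_flagged_unsplittable(self):
        img = self.BG.copy().astype(int)
        yy, xx = np.mgrid[0:60, 0:90]
        img[(np.hypot(xx - 40, yy - 30) <= 15)] = 100  # flat disc, no gradient
        blob = self._blob(img.astype(np.uint8))
        pieces, ok = split_overlapping(blob, 2, self.BG, start_threshold=25)
        assert not ok
        assert len(pieces) == 1 and pieces[0] is blob

    def test_already_separate_components_returned(self):
        img = self.BG.astype(float).copy()
        gradient_disc(img, 20, 30, 8, 120)
        gradient_disc(img, 60, 30, 8, 120)
        fg = np.abs(img - 200) >= 25
        ys, xs = np.nonzero(fg)
        blob = Blob(ys=ys, xs=xs, values=img.astype(np.uint8)[ys, xs])  # forced merge
        pieces, ok = split_overlapping(blob, 2, self.BG, start_threshold=25)
        assert ok and len(pieces) == 2

    def test_expected_count_below_two_rejected(self):
        with pytest.raises(ValueError):
            split_overlapping(point_blob(1, 1), 1, self.BG)


def run_tracker_on_scene(cfg, tracker_cfg, seg_threshold=25):
    frames, truth = synthetic_scene.generate_dataset(cfg)
    bg = estimate_background(frames[:: max(1, len(frames) // 20)], "mode")
    scfg = SegmentationConfig(threshold=seg_threshold, blob_size_range=(20, 100_000))
    tracker = Tracker(tracker_cfg, background=bg.image)
    for t in range(cfg.n_frames):
        tracker.advance_frame(segment_frame(frames[t], bg, scfg), t / cfg.fps)
    return tracker, truth


class TestTrackerEndToEnd:
    def test_clean_scene_one_segment_each_and_perfect_identity(self):
        cfg = synthetic_scene.SceneConfig(n_agents=2, n_frames=100, seed=2,
                                          frame_size=(256, 256), noise_sd=2.0)
        tracker, truth = run_tracker_on_scene(
            cfg, TrackerConfig(track_max_individuals=2, track_max_speed=500.0))
        assert len(tracker.individuals) == 2
        for ind in tracker.individuals.values():
            assert len(ind.segments) == 1
            assert len(ind.assignments) == 100
        sim, _ = synthetic_scene.score_identity_accuracy(truth, tracker.to_frame(), 256)
        assert sim == 1.0

    def test_hidden_agent_resumes_with_lost_segment(self):
        cfg = synthetic_scene.SceneConfig(n_agents=1, n_frames=40, seed=3,
                                          frame_size=(200, 200), noise_sd=0.0,
                                          speed_mean=1.0, speed_sd=0.2)
        frames, truth = synthetic_scene.generate_dataset(cfg)
        # hide the agent for frames 20..22 by pasting background over it
        bg = estimate_background(frames[::4], "mode")
        for f in range(20, 23):
            frames[f] = bg.image
        scfg = SegmentationConfig(threshold=25, blob_size_range=(20, 100_000))
        tracker = Tracker(TrackerConfig(track_max_individuals=1, track_max_speed=500.0,
                                        max_reassign_time=0.5), background=bg.image)
        for t in range(cfg.n_frames):
            tracker.advance_frame(segment_frame(frames[t], bg, scfg), t / cfg.fps)
        assert len(tracker.individuals) == 1
        ind = tracker.individuals[0]
        assert 20 not in ind.assignments and 23 in ind.assignments
        reasons = [s.reason for s in ind.segments]
        assert reasons[0] == "start" and "lost" in reasons

    def test_timestamp_jump_opens_gap_segment(self):
        cfg = synthetic_scene.SceneConfig(n_agents=1, n_frames=40, seed=4,
                                          frame_size=(200, 200), noise_sd=0.0,
                                          speed_mean=1.0, speed_sd=0.2)
        frames, _ = synthetic_scene.generate_dataset(cfg)
        bg = estimate_background(frames[::4], "mode")
        scfg = SegmentationConfig(threshold=25, blob_size_range=(20, 100_000))
        tracker = Tracker(TrackerConfig(track_max_individuals=1, track_max_speed=500.0,
                                        max_reassign_time=5.0), background=bg.image)
        t = 0.0
        for f in range(cfg.n_frames):
            t += 0.04 * (5.0 if f == 30 else 1.0)  # frame 30 arrives 5x late
            tracker.advance_frame(segment_frame(frames[f], bg, scfg), t)
        reasons = [s.reason for s in tracker.individuals[0].segments]
        assert "timestamp_gap" in reasons

    def test_initial_frame_identities_ordered_top_left_to_bottom_right(self):
        blobs = [point_blob(30, 30), point_blob(5, 5), point_blob(30, 5)]
        tracker = Tracker(TrackerConfig(track_max_individuals=3))
        tracker.advance_frame(blobs, 0.0)
        pos = {i: ind.last_position for i, ind in tracker.individuals.items()}
        assert pos[0] == (5.5, 5.5)
        assert pos[1] == (30.5, 5.5)
        assert pos[2] == (30.5, 30.5)

    def test_unknown_count_mode_creates_identities_for_new_blobs(self):
        tracker = Tracker(TrackerConfig(track_max_individuals="unknown",
                                        track_max_speed=300.0))
        tracker.advance_frame([point_blob(10, 10)], 0.0)
        tracker.advance_frame([point_blob(11, 10), point_blob(150, 150)], 0.04)
        assert len(tracker.individuals) == 2

    def test_no_blob_assigned_twice(self):
        cfg = synthetic_scene.SceneConfig(n_agents=4, n_frames=60, seed=9,
                                          frame_size=(256, 256), overlap_rate=20.0)
        tracker, _ = run_tracker_on_scene(
            cfg, TrackerConfig(track_max_individuals=4, track_max_speed=500.0))
        for f in range(60):
            blob_ids = [id(ind.assignments[f].blob)
                        for ind in tracker.individuals.values()
                        if f in ind.assignments and ind.assignments[f].blob is not None]
            assert len(blob_ids) == len(set(blob_ids))
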