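import math

import numpy as np
import pytest

from btx.tracking import Assignment, Individual
from btx.visual_id import (
    AccumulationExhausted,
    AccumulationState,
    ConsecutiveSegment,
    GlobalSegment,
    LinearBackend,
    MLPBackend,
    QualityMetrics,
    VisualIdConfig,
    accumulation_step,
    check_stopping,
    correct_switches,
    E_scale,
    eq2_score,
    final_epoch_cap,
    find_global_segments,
    frame_uniqueness,
    rank_global_segments,
    segment_quality,
    sig,
    split_into_segments,
    train_initial,
    uniqueness_threshold,
)


def direct_uniqueness(p):
    """Independent evaluation of the per-frame uniqueness definition."""
    uids = {}
    for row in p:
        m = int(np.argmax(row))
        uids[m] = max(uids.get(m, 0.0), float(row[m]))
    mean = sum(uids.values()) / len(uids)
    E = (1 + math.exp(-math.pi)) / (1 + math.exp(-math.pi * mean))
    return len(uids) / len(p) * E


class TestFrameUniqueness:
    def test_distinct_one_hot_scores_exactly_one(self):
        assert frame_uniqueness(np.eye(4)) == 1.0

    def test_worked_example(self):
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        expect = (2 / 2) * E_scale(0.85)
        assert frame_uniqueness(p) == pytest.approx(expect, abs=1e-12)
        assert frame_uniqueness(p) == pytest.approx(0.9757, abs=5e-4)

    def test_argmax_collision_halves_unique_fraction(self):
        collide = np.array([[0.9, 0.1], [0.8, 0.2]])
        distinct = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert frame_uniqueness(collide) < frame_uniqueness(distinct)
        # |uids| = 1 of 2 objects
        assert frame_uniqueness(collide) == pytest.approx(0.5 * E_scale(0.9), abs=1e-12)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_independent_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n_obj = int(rng.integers(1, 9))
        n_id = int(rng.integers(2, 9))
        p = rng.dirichlet(np.ones(n_id), size=n_obj)
        assert frame_uniqueness(p) == pytest.approx(direct_uniqueness(p), abs=1e-12)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            frame_uniqueness(np.zeros((0, 4)))


class TestEq2:
    def test_sig_midpoint(self):
        assert sig(0.5) == pytest.approx(0.5, abs=1e-15)

    def test_strictly_increasing_in_both_arguments(self):
        grid = np.linspace(0.01, 0.99, 15)
        for x in (0.2, 0.5, 0.8):
            vals = [eq2_score(p, x * 100, 100, 100) for p in grid]
            assert all(b > a for a, b in zip(vals, vals[1:]))
        for p in (0.2, 0.5, 0.8):
            vals = [eq2_score(p, x, 100, 100) for x in np.linspace(1, 199, 15)]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_large_sample_segment_beats_higher_probability(self):
        s_me = eq2_score(0.8, 100, 100, 10)
        s_he = eq2_score(0.9, 10, 10, 100)
        assert s_me == pytest.approx(1.797, abs=5e-3)
        assert s_he == pytest.approx(0.996, abs=5e-3)
        assert s_me > s_he


class TestThresholdArithmetic:
    def test_uniqueness_threshold_values(self):
        assert uniqueness_threshold(2) == pytest.approx(0.75)
        assert uniqueness_threshold(10) == pytest.approx(0.95)

    def test_threshold_monotone_in_n(self):
        ts = [uniqueness_threshold(n) for n in range(2, 40)]
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_final_epoch_cap(self):
        assert final_epoch_cap(150) == 37
        assert final_epoch_cap(8) == 3


class TestCorrectSwitches:
    def test_constant_predictions_no_split(self):
        assert correct_switches(np.zeros(300, dtype=int), 25) is None

    def test_persistent_flip_split_at_change(self):
        ids = np.array([0] * 200 + [1] * 200)
        assert correct_switches(ids, 25) == 200

    def test_single_frame_glitches_absorbed(self):
        ids = np.zeros(200, dtype=int)
        ids[50] = 1
        ids[120] = 2
        assert correct_switches(ids, 25) is None

    def test_short_lived_flip_not_split(self):
        ids = np.array([0] * 100 + [1] * 10 + [0] * 100)
        assert correct_switches(ids, 25) is None


def make_individual(ident, spans, xy=lambda f: (float(f), 0.0)):
    """spans: list of (start, end, reason) segments with every frame assigned."""
    ind = Individual(ident)
    for start, end, reason in spans:
        for f in range(start, end + 1):
            x, y = xy(f)
            first = f == start and ind.segments
            ind.add(Assignment(frame=f, time=f * 0.04, x=x, y=y, probability=0.9),
                    reason if (f == start and ind.segments) else None)
    return ind


class TestSegmentsAndGlobalSegments:
    def test_clean_trajectory_single_segment(self):
        inds = {0: make_individual(0, [(0, 99, None)])}
        segs = split_into_segments(inds)
        assert len(segs[0]) == 1
        assert (segs[0][0].start, segs[0][0].end) == (0, 99)

    def test_split_reasons_preserved(self):
        ind = make_individual(0, [(0, 49, None), (51, 80, "lost")])
        segs = split_into_segments({0: ind})[0]
        assert [s.reason for s in segs] == ["start", "lost"]

    def test_interval_intersection(self):
        inds = {0: make_individual(0, [(0, 100, None)]),
                1: make_individual(1, [(50, 150, None)])}
        segs = split_into_segments(inds)
        g = find_global_segments(segs, 2)
        assert len(g) == 1
        assert (g[0].start, g[0].end) == (50, 100)

    def test_untracked_individual_kills_global_segments(self):
        inds = {0: make_individual(0, [(0, 100, None)])}
        segs = split_into_segments(inds)
        segs[1] = []  # known individual that never got tracked
        assert find_global_segments(segs, 2) == []

    def test_staircase_matches_per_frame_oracle(self):
        spans = {0: [(0, 30, None), (32, 70, "lost"), (72, 99, "lost")],
                 1: [(0, 50, None), (52, 99, "uncertain")],
                 2: [(10, 99, None)]}
        inds = {i: make_individual(i, s) for i, s in spans.items()}
        segs = split_into_segments(inds)
        got = find_global_segments(segs, 3)
        # oracle: frame-by-frame membership in a single segment per individual
        def covering(i, f):
            for k, s in enumerate(segs[i]):
                if s.start <= f <= s.end:
                    return k
            return None

        expected = []
        run = None
        for f in range(0, 101):
            cov = tuple(covering(i, f) for i in spans)
            if f <= 99 and all(c is not None for c in cov):
                if run is None or cov != run[2]:
                    if run is not None:
                        expected.append((run[0], run[1]))
                    run = [f, f, cov]
                else:
                    run[1] = f
            else:
                if run is not None:
                    expected.append((run[0], run[1]))
                    run = None
        assert [(g.start, g.end) for g in got] == expected


class TestSegmentQuality:
    def _gseg(self, inds, start, end):
        segs = split_into_segments(inds)
        return GlobalSegment(start=start, end=end,
                             segments={i: segs[i][0] for i in inds})

    def test_stationary_individuals_visit_zero_cells(self):
        inds = {0: make_individual(0, [(0, 50, None)], xy=lambda f: (5.0, 5.0)),
                1: make_individual(1, [(0, 50, None)], xy=lambda f: (90.0, 90.0))}
        q = segment_quality(self._gseg(inds, 0, 50), inds, (100, 100), grid=10)
        assert q.min_cells_visited == 0
        assert q.avg_samples == pytest.approx(51.0)

    def test_minimum_over_individuals(self):
        # individual 0 crosses 5 cell borders, individual 1 crosses 10
        inds = {0: make_individual(0, [(0, 50, None)],
                                   xy=lambda f: (min(f, 5) * 10.0 + 5.0, 5.0)),
                1: make_individual(1, [(0, 50, None)],
                                   xy=lambda f: (min(f, 10) * 10.0 % 100 + 4.0, 55.0))}
        q = segment_quality(self._gseg(inds, 0, 50), inds, (100, 100), grid=10)
        assert q.min_cells_visited == 5

    def test_arena_sweep_beats_tight_circling(self):
        sweep = make_individual(0, [(0, 99, None)],
                                xy=lambda f: (f, f))  # diagonal across the arena
        circle = make_individual(1, [(0, 99, None)],
                                 xy=lambda f: (55 + 3 * math.cos(0.47 * f),
                                               55 + 3 * math.sin(0.47 * f)))
        inds = {0: sweep, 1: circle}
        segs = split_into_segments(inds)
        g0 = GlobalSegment(0, 99, {0: segs[0][0]})
        g1 = GlobalSegment(0, 99, {1: segs[1][0]})
        q_sweep = segment_quality(g0, inds, (100, 100), grid=10)
        q_circ = segment_quality(g1, inds, (100, 100), grid=10)
        assert q_sweep.min_cells_visited > q_circ.min_cells_visited


class TestRankGlobalSegments:
    def _gseg(self, start, end, cells, samples):
        return GlobalSegment(start=start, end=end, segments={},
                             metrics=QualityMetrics(cells, samples))

    def test_keep_per_bin_caps_survivors(self):
        gs = [self._gseg(k * 10, k * 10 + 5, cells=k, samples=10.0) for k in range(20)]
        ranked = rank_global_segments(gs, video_length=1000, keep_per_bin=4)
        # all 20 candidates fall into the first quarter; only 4 survive
        assert len(ranked) == 4
        assert [g.metrics.min_cells_visited for g in ranked] == [19, 18, 17, 16]

    def test_ties_resolved_by_avg_samples(self):
        a = self._gseg(0, 10, cells=5, samples=50.0)
        b = self._gseg(20, 30, cells=5, samples=80.0)
        ranked = rank_global_segments([a, b], video_length=200, keep_per_bin=4)
        assert ranked[0] is b

    def test_survivors_dominate_discarded_within_bins(self, rng):
        gs = [self._gseg(int(rng.integers(0, 900)), 0, cells=int(rng.integers(0, 40)),
                         samples=float(rng.integers(1, 100))) for _ in range(40)]
        for g in gs:
            g.end = g.start + 20
        ranked = rank_global_segments(gs, video_length=1000, keep_per_bin=4)
        kept = set(map(id, ranked))
        bins = {}
        for g in gs:
            q = min(3, int(4 * g.middle / 1000))
            bins.setdefault(q, []).append(g)
        for q, members in bins.items():
            kept_m = [g for g in members if id(g) in kept]
            lost_m = [g for g in members if id(g) not in kept]
            for k in kept_m:
                for l in lost_m:
                    assert (k.metrics.min_cells_visited, k.metrics.avg_samples) >= \
                           (l.metrics.min_cells_visited, l.metrics.avg_samples)

    def test_round_robin_starts_from_best_overall(self):
        gs = [self._gseg(100, 120, 3, 5.0), self._gseg(600, 620, 9, 5.0),
              self._gseg(900, 920, 1, 5.0)]
        ranked = rank_global_segments(gs, video_length=1000, keep_per_bin=4)
        assert ranked[0].metrics.min_cells_visited == 9


class TestBackends:
    @staticmethod
    def dataset(rng, n_classes=3, n=40, size=(24, 24)):
        imgs, labels = [], []
        for cls in range(n_classes):
            base = np.zeros(size)
            base[4 + 4 * cls: 8 + 4 * cls, 4:20] = 150  # class-specific band
            for _ in range(n):
                imgs.append(np.clip(base + rng.normal(0, 8, size), 0, 255))
                labels.append(cls)
        return np.stack(imgs), np.array(labels)

    def test_deterministic_per_seed(self, rng):
        x, y = self.dataset(rng)
        b1, b2 = LinearBackend(3, seed=9), LinearBackend(3, seed=9)
        b1.fit(x, y, x[::5], y[::5], max_epochs=40)
        b2.fit(x, y, x[::5], y[::5], max_epochs=40)
        assert all(np.array_equal(u, v) for u, v in zip(b1.weights, b2.weights))
        assert np.array_equal(b1.predict(x), b2.predict(x))

    def test_prediction_rows_sum_to_one(self, rng):
        x, y = self.dataset(rng)
        b = LinearBackend(3, seed=1)
        b.fit(x, y, max_epochs=10)
        p = b.predict(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all()

    @pytest.mark.parametrize("backend_cls", [LinearBackend, MLPBackend])
    def test_learnable_classes_reach_high_accuracy(self, rng, backend_cls):
        x, y = self.dataset(rng)
        b = backend_cls(3, seed=2)
        b.fit(x, y, x[::5], y[::5], max_epochs=150)
        assert (b.predict(x).argmax(1) == y).mean() > 0.95

    def test_unlearnable_classes_stop_by_plateau_at_chance(self, rng):
        x = rng.normal(100, 5, (90, 24, 24))
        y = np.repeat(np.arange(3), 30)
        b = LinearBackend(3, seed=2)
        hist = b.fit(x, y, x[::5], y[::5], max_epochs=150)
        assert hist["stop_reason"] in ("plateau", "overfitting")
        assert hist["epochs"] < 150

    def test_epoch_cap_honored(self, rng):
        x, y = self.dataset(rng)
        b = LinearBackend(3, seed=3)
        hist = b.fit(x, y, max_epochs=7)
        assert hist["epochs"] <= 7

    def test_snapshot_restore_round_trip(self, rng):
        x, y = self.dataset(rng)
        b = LinearBackend(3, seed=4)
        b.fit(x, y, max_epochs=15)
        snap = b.snapshot()
        p1 = b.predict(x)
        b.fit(x, y, max_epochs=10)  # move the weights
        b.restore(snap)
        assert np.array_equal(b.predict(x), p1)


def crop_dataset(rng, n_classes, n_per_class, size=(16, 16)):
    imgs = {}
    for cls in range(n_classes):
        base = np.zeros(size)
        base[2 + 3 * cls: 5 + 3 * cls, 2:14] = 160
        imgs[cls] = np.stack([np.clip(base + rng.normal(0, 6, size), 0, 255)
                              for _ in range(n_per_class)])
    return imgs


def build_state_with_model(rng, n=3, n_images=40):
    """Initial training on a constructed global segment of n individuals."""
    imgs = crop_dataset(rng, n, n_images)
    segments = {}
    for ident in range(n):
        seg = ConsecutiveSegment(individual=ident, start=0, end=n_images - 1,
                                 frames=list(range(n_images)), images=imgs[ident])
        segments[ident] = seg
    gseg = GlobalSegment(0, n_images - 1, segments,
                         metrics=QualityMetrics(5, float(n_images)))
    sample_frames = {f: np.stack([imgs[i][f] for i in range(n)])
                     for f in range(0, n_images, 4)}
    backend = LinearBackend(n, seed=5)
    cfg = VisualIdConfig(seed=5, min_images_per_class=5)
    state = train_initial([gseg], backend, cfg, video_length=n_images,
                          sample_frames=sample_frames, n_individuals=n)
    return state, backend, sample_frames, imgs


class TestTrainingUnits:
    def test_initial_unit_learns_and_snapshots(self, rng):
        state, backend, sample_frames, _ = build_state_with_model(rng)
        assert state.best_uniqueness > 0.9
        assert not state.failed_initial
        assert state.best_state is not None
        assert state.status[state.added[0].key] == "added"

    def test_small_class_candidate_rejected_next_tried(self, rng):
        imgs = crop_dataset(rng, 2, 30)
        good = {i: ConsecutiveSegment(individual=i, start=0, end=29,
                                      frames=list(range(30)), images=imgs[i])
                for i in range(2)}
        starving = {i: ConsecutiveSegment(individual=i, start=40, end=42,
                                          frames=[40, 41, 42], images=imgs[i][:3])
                    for i in range(2)}
        g_bad = GlobalSegment(40, 42, starving, metrics=QualityMetrics(9, 3.0))
        g_good = GlobalSegment(0, 29, good, metrics=QualityMetrics(1, 30.0))
        sample_frames = {f: np.stack([imgs[i][f] for i in range(2)])
                         for f in range(0, 30, 3)}
        backend = LinearBackend(2, seed=6)
        state = train_initial([g_bad, g_good], backend, VisualIdConfig(seed=6),
                              30, sample_frames, 2)
        assert state.added[0] is g_good  # starving candidate skipped

    def test_no_viable_candidate_raises(self, rng):
        backend = LinearBackend(2, seed=6)
        with pytest.raises(AccumulationExhausted):
            train_initial([], backend, VisualIdConfig(), 10, {}, 2)

    def test_unlearnable_appearance_flags_failure(self, rng):
        n, n_images = 3, 40
        flat = {i: rng.normal(100, 5, (n_images, 16, 16)) for i in range(n)}
        segments = {i: ConsecutiveSegment(individual=i, start=0, end=n_images - 1,
                                          frames=list(range(n_images)), images=flat[i])
                    for i in range(n)}
        gseg = GlobalSegment(0, n_images - 1, segments,
                             metrics=QualityMetrics(5, float(n_images)))
        sample_frames = {f: np.stack([flat[i][f] for i in range(n)])
                         for f in range(0, n_images, 4)}
        backend = LinearBackend(n, seed=7)
        state = train_initial([gseg], backend, VisualIdConfig(seed=7),
                              n_images, sample_frames, n)
        assert state.failed_initial

    def test_final_unit_keeps_best_when_degraded(self, rng):
        state, backend, sample_frames, _ = build_state_with_model(rng)
        best_before = state.best_uniqueness
        snap = state.best_state

        class Sabotaged(LinearBackend):
            def fit(self, *a, **kw):
                # wreck the weights instead of training
                self.weights = [np.zeros_like(w) for w in self.weights]
                return {"stop_reason": "sabotage", "epochs": 1}

        sab = Sabotaged(3, seed=5)
        sab.restore(snap)
        sab.n_classes = 3
        from btx.visual_id import train_final

        train_final(state, sab, sample_frames)
        assert state.best_uniqueness == pytest.approx(best_before)
        # the degraded model was rolled back to the best snapshot
        ref = LinearBackend(3, seed=5)
        ref.restore(snap)
        probe = sample_frames[0]
        assert np.allclose(sab.predict(probe), ref.predict(probe))


class TestAccumulationRules:
    def test_ninety_nine_percent_rejection_arithmetic(self):
        # post-training mean uniqueness 0.97 against best 0.99
        assert 0.97 < 0.99 * 0.99

    def test_implausible_candidate_marked_failed(self, rng):
        state, backend, sample_frames, imgs = build_state_with_model(rng)
        # candidate whose two individuals show the SAME appearance (class 0)
        dup = {0: ConsecutiveSegment(individual=0, start=50, end=89,
                                     frames=list(range(50, 90)), images=imgs[0]),
               1: ConsecutiveSegment(individual=1, start=50, end=89,
                                     frames=list(range(50, 90)), images=imgs[0]),
               2: ConsecutiveSegment(individual=2, start=50, end=89,
                                     frames=list(range(50, 90)), images=imgs[2])}
        cand = GlobalSegment(50, 89, dup, metrics=QualityMetrics(3, 40.0))
        state.candidates = state.added + [cand]
        before = len(state.added)
        with pytest.raises(AccumulationExhausted):
            accumulation_step(state, backend, sample_frames)
        assert state.status[cand.key] == "failed"
        assert len(state.added) == before  # training set unchanged

    def test_uprev_half_disqualification(self, rng):
        state, backend, sample_frames, imgs = build_state_with_model(rng)
        state.steps = 6  # past the five-step grace period
        state.best_uniqueness = 0.9
        weak = {i: ConsecutiveSegment(individual=i, start=50, end=89,
                                      frames=list(range(50, 90)),
                                      images=rng.normal(100, 5, (40, 16, 16)))
                for i in range(3)}
        cand = GlobalSegment(50, 89, weak, metrics=QualityMetrics(3, 40.0))
        state.candidates = state.added + [cand]
        with pytest.raises(AccumulationExhausted):
            accumulation_step(state, backend, sample_frames)
        assert state.status[cand.key] == "rejected"


class TestCheckStopping:
    def _state(self, n, uniqueness, video_length=100, added=()):
        cfg = VisualIdConfig()
        st = AccumulationState(n_individuals=n, config=cfg,
                               label_map={i: i for i in range(n)},
                               video_length=video_length)
        st.best_uniqueness = uniqueness
        st.added = list(added)
        return st

    def test_high_uniqueness_stops_even_with_gaps(self):
        st = self._state(2, 0.80)
        assert check_stopping(st) == "done"  # 0.80 > 1 - 0.5/2

    def test_low_uniqueness_with_gaps_continues(self):
        st = self._state(2, 0.60)
        assert check_stopping(st) == "continue"

    def test_small_coverage_gaps_stop(self):
        seg = ConsecutiveSegment(individual=0, start=0, end=89)
        seg2 = ConsecutiveSegment(individual=1, start=0, end=89)
        g = GlobalSegment(0, 89, {0: seg, 1: seg2})
        st = self._state(2, 0.60, video_length=100, added=[g])
        # gaps are 10 frames < 25% of 100 for both individuals
        assert check_stopping(st) == "done"
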