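from dataclasses import replace

import numpy as np
import pytest

from weeviltrack.clearmot_eval import evaluate_tracking
from weeviltrack.mot_io import BoundingBox, Detection
from weeviltrack.synth_scenarios import ScenarioConfig, generate
from weeviltrack.tracker_core import (
    HistoryRecord,
    TargetHistoryStore,
    Track,
    TrackStatus,
    Tracker,
    TrackerConfig,
    count_targets,
    new_identity,
    update_history,
    validate_id,
)

from conftest import box


def det(frame, b, conf=0.9):
    return Detection(frame, b, conf)


def store_with(*identities_and_records):
    store = TargetHistoryStore()
    for ident, records in identities_and_records:
        for f, (x, y) in records:
            store.add(ident, f, (x, y), BoundingBox(x - 5, y - 5, 10, 10))
    return store


class TestNewIdentity:
    def test_empty_store_starts_at_one(self):
        assert new_identity(TargetHistoryStore(), []) == 1

    def test_max_plus_one_over_store(self):
        store = store_with((1, [(1, (0, 0))]), (2, [(1, (10, 10))]),
                           (5, [(1, (20, 20))]))
        assert new_identity(store, []) == 6

    def test_history_outlives_deletion(self):
        """A deleted identity in the store still raises the max."""
        store = store_with((7, [(1, (0, 0))]))
        live = [Track(identity=3, motion=None)]
        assert new_identity(store, live) == 8

    def test_issued_identities_strictly_increase(self):
        store = TargetHistoryStore()
        issued = []
        for f in range(1, 6):
            i = new_identity(store, [])
            store.add(i, f, (0, 0), box())
            issued.append(i)
        assert issued == sorted(set(issued)) == [1, 2, 3, 4, 5]


class TestValidateId:
    HIST = [HistoryRecord(10, (100.0, 100.0), BoundingBox(95, 95, 10, 10))]

    def test_zero_speed_passes(self):
        assert validate_id(self.HIST, (11, (100.0, 100.0)), 50, 30)

    def test_gap_exceeded_fails(self):
        assert not validate_id(self.HIST, (45, (100.0, 100.0)), 50, 30)

    def test_boundary_speed_inclusive(self):
        # 100 px over 4 frames at max_speed 25: exactly on the limit
        assert validate_id(self.HIST, (14, (200.0, 100.0)), 25, 30)
        assert not validate_id(self.HIST, (14, (200.1, 100.0)), 25, 30)

    def test_non_increasing_frame_raises(self):
        with pytest.raises(ValueError):
            validate_id(self.HIST, (10, (0.0, 0.0)), 50, 30)

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            validate_id([], (11, (0.0, 0.0)), 50, 30)


class TestUpdateHistory:
    CFG = TrackerConfig(validation_max_speed=50, validation_max_gap=30)

    def _track(self, ident, x, y):
        t = Track(identity=ident, motion=None)
        t.__dict__["_fixed_box"] = BoundingBox(x - 5, y - 5, 10, 10)
        return t

    def test_first_observation_creates_entry(self):
        store = TargetHistoryStore()
        t = Track(identity=4, motion=None)
        update_history(store, t, 3, self.CFG, box=BoundingBox(0, 0, 10, 10))
        assert 4 in store and store.length(4) == 1

    def test_plausible_observation_appended(self):
        store = store_with((2, [(1, (100, 100))]))
        t = Track(identity=2, motion=None)
        update_history(store, t, 2, self.CFG, box=BoundingBox(107, 95, 10, 10))
        assert t.identity == 2 and store.length(2) == 2

    def test_implausible_jump_reassigns_max_plus_one(self):
        """1414 px in one frame with max_speed 50 forces a fresh identity;
        the old entry is preserved."""
        store = store_with((2, [(1, (0, 0))]), (9, [(1, (500, 500))]))
        t = Track(identity=2, motion=None)
        update_history(store, t, 2, self.CFG,
                       box=BoundingBox(995, 995, 10, 10))  # center (1000,1000)
        assert t.identity == 10
        assert store.length(2) == 1 and store.length(10) == 1

    def test_stale_frame_raises(self):
        store = store_with((2, [(5, (0, 0))]))
        t = Track(identity=2, motion=None)
        with pytest.raises(ValueError):
            update_history(store, t, 5, self.CFG, box=BoundingBox(0, 0, 10, 10))


class TestCountTargets:
    def test_empty_store(self):
        assert count_targets(TargetHistoryStore(), 3) == 0

    def test_min_length_filter(self):
        store = store_with(
            (1, [(f, (0, 0 + f)) for f in range(1, 6)]),
            (2, [(1, (50, 50))]),
        )
        assert count_targets(store, 3) == 1
        assert count_targets(store, 1) == 2


def run_tracker(detections, config=None):
    tracker = Tracker(config or TrackerConfig())
    tracker.run(detections)
    return tracker


class TestTrackerLifecycle:
    def test_single_target_confirms_with_identity_one(self):
        tracker = Tracker(TrackerConfig(n_init=3))
        b = box(100, 100, 20, 20)
        out = []
        for f in range(1, 4):
            out = tracker.step(f, [det(f, b)])
        assert len(out) == 1
        assert out[0].identity == 1
        assert out[0].status is TrackStatus.CONFIRMED

    def test_track_deleted_after_max_age(self):
        cfg = TrackerConfig(n_init=2, max_age=3)
        tracker = Tracker(cfg)
        b = box(100, 100, 20, 20)
        for f in range(1, 4):
            tracker.step(f, [det(f, b)])
        assert len(tracker.tracks) == 1
        for f in range(4, 4 + cfg.max_age + 1):
            tracker.step(f, [])
        assert tracker.tracks == []

    def test_non_increasing_frame_rejected(self):
        tracker = Tracker()
        tracker.step(1, [])
        with pytest.raises(ValueError):
            tracker.step(1, [])

    def test_two_separated_targets_tracked_cleanly(self):
        """Two well-separated constant-velocity targets over 30 noise-free
        frames: 2 confirmed tracks, perfect MOTA, no identity switches."""
        cfg = ScenarioConfig(n_targets=2, n_frames=30, arena=(600, 300),
                             base_speed=4.0, turn_probability=0.0, lanes=True,
                             seed=5)
        scenario = generate(cfg)
        tracker = run_tracker(scenario.detections,
                              TrackerConfig.for_arena(600, 300))
        report = evaluate_tracking(scenario.gt, tracker.results(),
                                   count_pred=tracker.count())
        assert report.mota == 100.0
        assert report.ids_total == 0
        assert tracker.count() == 2


class TestZeroNoiseRecovery:
    def test_planted_count_recovered(self):
        """Noise-free 17-target scenario: the unique-identity count equals
        the planted number of targets."""
        from weeviltrack.synth_scenarios import paper_like_fixture

        scenario = paper_like_fixture(zero_noise=True)
        tracker = run_tracker(scenario.detections,
                              TrackerConfig.for_arena(*scenario.config.arena))
        assert tracker.count() == 17


class TestHistoryModuleAblation:
    def test_identity_recovered_across_long_occlusion(self):
        """A target occluded longer than max_age loses its track; with the
        history store its old identity is resumed, without it a new one is
        minted."""
        cfg = ScenarioConfig(n_targets=1, n_frames=80, arena=(600, 300),
                             base_speed=2.0, turn_probability=0.0, lanes=True,
                             occlusion_windows=((1, 30, 42),), seed=3)
        scenario = generate(cfg)
        trk_cfg = TrackerConfig.for_arena(600, 300, max_age=8)
        with_history = run_tracker(scenario.detections, trk_cfg)
        without = run_tracker(scenario.detections,
                              replace(trk_cfg, history_enabled=False))
        ids_on = {o.identity for o in with_history.results().all_objects()}
        ids_off = {o.identity for o in without.results().all_objects()}
        assert len(ids_on) == 1
        assert len(ids_off) == 2

    def test_ids_not_increased_by_history_module(self):
        """Across seeded occlusion scenarios, total identity switches with
        the history module enabled never exceed the total with it disabled."""
        base = ScenarioConfig(n_targets=4, n_frames=120, arena=(800, 450),
                              base_speed=4.0, turn_probability=0.02,
                              fn_rate=0.02, jitter_std=0.5,
                              occlusion_windows=((1, 30, 70), (3, 60, 100)))
        totals = {True: 0, False: 0}
        for seed in range(1, 21):
            scenario = generate(replace(base, seed=seed))
            for enabled in (True, False):
                cfg = TrackerConfig.for_arena(800, 450, history_enabled=enabled)
                tracker = run_tracker(scenario.detections, cfg)
                report = evaluate_tracking(scenario.gt, tracker.results())
                totals[enabled] += report.ids_total
        assert totals[True] <= totals[False]
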