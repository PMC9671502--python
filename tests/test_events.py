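"""Initiation detection, lockout filtering, trial pooling, quiescence, stereotypy."""

import numpy as np
import pytest

from premove import (BodyTrack, EventTable, LockoutSpec, apply_lockout,
                     detect_initiations, pool_lockout_trials,
                     select_quiescent_bouts, stereotypy_embedding)
from premove.exceptions import InsufficientDataError

FPS_VIDEO = 15.0


def _track(n=1500, jumps=(), seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    xy = np.full((n, 2), 100.0) + noise * rng.standard_normal((n, 2))
    for frame, dxy in jumps:
        xy[frame:] += dxy
    return xy


class TestDetectInitiations:
    def test_constant_track_has_no_initiations(self):
        assert detect_initiations(_track(), FPS_VIDEO).size == 0

    def test_single_jump_gives_one_initiation(self):
        xy = _track(jumps=[(700, (50.0, 0.0))])
        times = detect_initiations(xy, FPS_VIDEO)
        assert times.size == 1
        assert abs(times[0] - 700 / FPS_VIDEO) < 31 / FPS_VIDEO  # within the smoothing span

    def test_refractory_keeps_first_of_close_pair(self):
        xy = _track(jumps=[(300, (50.0, 0.0)), (315, (0.0, 50.0))])  # 1 s apart
        times = detect_initiations(xy, FPS_VIDEO, refractory_s=3.0)
        assert times.size == 1
        xy = _track(jumps=[(300, (50.0, 0.0)), (600, (0.0, 50.0))])  # 20 s apart
        assert detect_initiations(xy, FPS_VIDEO, refractory_s=3.0).size == 2


class TestApplyLockout:
    def test_paper_style_enumeration(self):
        """Rewarded {5, 20, 40}, unrewarded {38}, lockout 15: only 20 survives."""
        events = EventTable({"lever_rewarded": [5.0, 20.0, 40.0],
                             "lever_unrewarded": [38.0]})
        out = apply_lockout(events, "lever_rewarded", LockoutSpec(lockout_s=15.0))
        assert out.tolist() == [20.0]

    def test_zero_lockout_keeps_everything(self):
        events = EventTable({"lever_rewarded": [1.0, 2.0, 3.0]})
        out = apply_lockout(events, "lever_rewarded", LockoutSpec(lockout_s=0.0))
        assert out.tolist() == [1.0, 2.0, 3.0]

    def test_final_bin_edge_allowance(self):
        """A blocking movement inside the very last 0.250-s bin before the
        target is tolerated when edge_allowance is on, not otherwise."""
        events = EventTable({"lever_rewarded": [10.0], "lick": [9.9]})
        spec = LockoutSpec(lockout_s=3.0, blocked_kinds=("lick",))
        assert apply_lockout(events, "lever_rewarded", spec).tolist() == [10.0]
        spec_strict = LockoutSpec(lockout_s=3.0, blocked_kinds=("lick",),
                                  edge_allowance=False)
        assert apply_lockout(events, "lever_rewarded", spec_strict).size == 0

    def test_first_bin_edge_allowance(self):
        events = EventTable({"lever_rewarded": [10.0], "lick": [7.1]})
        spec = LockoutSpec(lockout_s=3.0, blocked_kinds=("lick",))
        assert apply_lockout(events, "lever_rewarded", spec).tolist() == [10.0]

    def test_underflow_dropped(self):
        events = EventTable({"lever_rewarded": [2.0, 30.0]})
        out = apply_lockout(events, "lever_rewarded", LockoutSpec(lockout_s=5.0))
        assert out.tolist() == [30.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_lockout_duration(self, seed):
        rng = np.random.default_rng(seed)
        events = EventTable({
            "lever_rewarded": np.sort(rng.uniform(0, 300, 40)),
            "lick": np.sort(rng.uniform(0, 300, 120)),
        })
        spec = lambda L: LockoutSpec(lockout_s=L, blocked_kinds=("lick",))
        counts = [apply_lockout(events, "lever_rewarded", spec(L)).size
                  for L in (0.0, 1.0, 3.0, 6.0, 12.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_subset_of_input(self):
        rng = np.random.default_rng(1)
        events = EventTable({"lever_rewarded": np.sort(rng.uniform(0, 200, 30)),
                             "lever_unrewarded": np.sort(rng.uniform(0, 200, 30))})
        out = apply_lockout(events, "lever_rewarded", LockoutSpec(lockout_s=10.0))
        assert set(out) <= set(events.times("lever_rewarded"))


class TestPoolLockoutTrials:
    def test_503_trials_give_10_groups(self):
        groups = pool_lockout_trials(503)
        assert len(groups) == 10
        assert groups[0] == (0, 200)
        assert groups[-1] == (450, 503)

    def test_exactly_group_size(self):
        # trailing windows are emitted while they still hold min_size trials
        assert pool_lockout_trials(200) == [(0, 200), (50, 200), (100, 200), (150, 200)]

    def test_too_few_trials_error(self):
        with pytest.raises(InsufficientDataError):
            pool_lockout_trials(49)

    @pytest.mark.parametrize("n", [50, 77, 200, 250, 503, 1000])
    def test_every_trial_covered(self, n):
        groups = pool_lockout_trials(n)
        covered = np.zeros(n, dtype=bool)
        for s, e in groups:
            covered[s:e] = True
        assert covered.all()


class TestQuiescentBouts:
    def test_rules(self):
        events = EventTable({
            "left_paw": [50.0, 120.0, 200.0],
            "lick": [48.0, 150.0],            # 2 s before the 50 s initiation
            "lever_rewarded": [124.0],        # 4 s after the 120 s initiation
        })
        out = select_quiescent_bouts(events)
        # 50 excluded by body rule, 120 by the lever post-window, 200 survives
        assert out["time_s"].tolist() == [200.0]
        assert out["quiescence_s"].iloc[0] == pytest.approx(50.0)  # since lick at 150

    def test_may_return_empty(self):
        events = EventTable({"left_paw": [10.0], "lick": [9.0]})
        assert len(select_quiescent_bouts(events)) == 0


class TestStereotypyEmbedding:
    def _tracks(self, pattern_frames, n=3000):
        xy = _track(n=n, jumps=[(f, (40.0, 0.0)) for f in pattern_frames])
        return BodyTrack(features={"left_paw": xy,
                                   "right_paw": _track(n=n)}, fps_video=FPS_VIDEO)

    def test_identical_trials_coincide(self):
        # the same movement pattern precedes every event
        evs = [60.0, 90.0, 120.0]
        frames = [int((t - 2.0) * FPS_VIDEO) for t in evs]
        tracks = self._tracks(frames)
        emb = stereotypy_embedding(tracks, evs, window_s=(-5.0, 0.0))
        assert np.allclose(emb, emb[0], atol=1e-9)

    def test_all_zero_patterns_error(self):
        from premove.exceptions import DegenerateDataError
        tracks = self._tracks([])
        with pytest.raises(DegenerateDataError):
            stereotypy_embedding(tracks, [60.0, 90.0, 120.0], window_s=(-5.0, 0.0))

    def test_two_patterns_two_clusters_and_centered(self):
        # left paw moves 2 s before events at 60/120/180 s, not before the others
        frames = [int((t - 2.0) * FPS_VIDEO) for t in (60.0, 120.0, 180.0)]
        tracks = self._tracks(frames)
        evs = [60.0, 120.0, 180.0, 90.0, 150.0, 195.0]
        emb = stereotypy_embedding(tracks, evs, window_s=(-5.0, 0.0))
        assert np.allclose(emb.mean(axis=0), 0.0, atol=1e-8)   # PCA scores centered
        d = np.linalg.norm(emb[:3].mean(axis=0) - emb[3:].mean(axis=0))
        assert d > 1.0
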