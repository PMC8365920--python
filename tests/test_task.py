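"""Reward-system tests: footstep ledger, targets, velocity field."""

import numpy as np
import pytest

from planargait.task import (EpisodeResult, FootstepLedger, RewardConfig,
                             TargetSpec, TaskScorer, VelocityField,
                             accumulate_step, alive_increment, close_footstep,
                             detect_footstep_event, sample_target,
                             total_reward, update_target)

CFG = RewardConfig()
DT = CFG.dt


class TestAlive:
    def test_increment_is_printed_constant(self):
        assert alive_increment(CFG) == 0.1

    def test_full_episode_sum(self):
        assert 2500 * alive_increment(CFG) == pytest.approx(250.0)

    def test_fallen_episode_partial_sum(self):
        assert 100 * alive_increment(CFG) == pytest.approx(10.0)


class TestFootstepDetection:
    def _feed(self, ledger, seq):
        """seq: list of (prev, curr) per-foot contact pairs."""
        events = []
        prev = np.array([True, True])
        for curr in seq:
            curr = np.asarray(curr, bool)
            events.append(detect_footstep_event(ledger, prev, curr, DT, CFG))
            prev = curr
        return events

    def test_static_feet_no_event(self):
        ledger = FootstepLedger()
        events = self._feed(ledger, [[1, 1]] * 50)
        assert all(e == "none" for e in events)

    def test_touchdown_after_swing_is_new_step(self):
        ledger = FootstepLedger()
        seq = [[1, 1]] * 10 + [[1, 0]] * 40 + [[1, 1]]
        events = self._feed(ledger, seq)
        assert events[-1] == "new_step"
        assert all(e == "none" for e in events[:-1])

    def test_contact_chatter_filtered(self):
        # 10 ms airborne blip is below the 50 ms swing minimum
        ledger = FootstepLedger()
        seq = [[1, 1]] * 10 + [[1, 0]] * 1 + [[1, 1]] * 5
        events = self._feed(ledger, seq)
        assert all(e == "none" for e in events)

    def test_forced_closure_during_standing(self):
        ledger = FootstepLedger()
        n_forced = int(CFG.forced_closure / DT) + 1
        events = []
        prev = np.array([True, True])
        for _ in range(n_forced + 5):
            e = detect_footstep_event(ledger, prev, prev, DT, CFG)
            accumulate_step(ledger, np.zeros(2), np.zeros(2),
                            np.zeros(22), DT)
            if e == "new_step":
                events.append(ledger.open_duration - DT)
                close_footstep(ledger, CFG)
        assert len(events) == 1
        assert events[0] == pytest.approx(CFG.forced_closure, abs=DT)


class TestAccumulateAndClose:
    def test_zero_error_integral(self):
        ledger = FootstepLedger()
        v = np.array([1.3, 0.0])
        for _ in range(50):
            accumulate_step(ledger, v, v, np.zeros(22), DT)
        assert np.allclose(ledger.open_velocity_integral, 0.0)

    def test_zero_mean_fluctuation_cancels(self):
        """c_v sees only the average velocity, not within-step fluctuation."""
        ledger = FootstepLedger()
        v0 = np.array([1.3, 0.0])
        for i in range(100):
            wig = np.array([0.2 * (1 if i % 2 == 0 else -1), 0.0])
            accumulate_step(ledger, v0 + wig, v0, np.zeros(22), DT)
        assert np.allclose(ledger.open_velocity_integral, 0.0, atol=1e-12)

    def test_constant_error_hand_integral(self):
        ledger = FootstepLedger()
        for _ in range(50):  # 0.5 s
            accumulate_step(ledger, np.array([1.0, 0.0]),
                            np.array([1.3, 0.0]), np.zeros(22), DT)
        assert ledger.open_velocity_integral == pytest.approx(
            [-0.15, 0.0], abs=1e-12)

    def test_close_zero_cost_full_second(self):
        ledger = FootstepLedger()
        for _ in range(100):
            accumulate_step(ledger, np.zeros(2), np.zeros(2),
                            np.zeros(22), DT)
        r, _ = close_footstep(ledger, CFG)
        assert r == pytest.approx(10.0, abs=1e-9)

    def test_close_velocity_cost_worked_example(self):
        # 0.5 s at 0.3 m/s error: 10*0.5 - 3*0.15 = 4.55
        ledger = FootstepLedger()
        for _ in range(50):
            accumulate_step(ledger, np.array([1.0, 0.0]),
                            np.array([1.3, 0.0]), np.zeros(22), DT)
        r, _ = close_footstep(ledger, CFG)
        assert r == pytest.approx(4.55, abs=1e-9)

    def test_close_effort_cost_worked_example(self):
        # 0.5 s, one muscle at 0.5: 5 - 1*(0.25*0.5) = 4.875
        ledger = FootstepLedger()
        acts = np.zeros(22)
        acts[7] = 0.5
        for _ in range(50):
            accumulate_step(ledger, np.zeros(2), np.zeros(2), acts, DT)
        r, _ = close_footstep(ledger, CFG)
        assert r == pytest.approx(4.875, abs=1e-9)

    def test_zero_duration_close_warns(self):
        ledger = FootstepLedger()
        with pytest.warns(UserWarning):
            r, _ = close_footstep(ledger, CFG)
        assert r == 0.0

    def test_records_are_appended_immutably(self):
        ledger = FootstepLedger()
        accumulate_step(ledger, np.zeros(2), np.zeros(2), np.zeros(22), DT)
        close_footstep(ledger, CFG)
        assert ledger.i_step == 1
        assert ledger.open_duration == 0.0
        assert len(ledger.records) == 1


class TestTargets:
    def test_sampling_deterministic_per_seed(self):
        a = sample_target(np.random.default_rng(42), np.zeros(2), 1, CFG)
        b = sample_target(np.random.default_rng(42), np.zeros(2), 1, CFG)
        assert np.array_equal(a.location, b.location)
        assert a.required_dwell == b.required_dwell

    def test_dwell_and_annulus_distributions(self):
        rng = np.random.default_rng(0)
        dwells, dists = [], []
        for _ in range(10_000):
            t = sample_target(rng, np.zeros(2), 1, CFG)
            dwells.append(t.required_dwell)
            dists.append(np.linalg.norm(t.location))
        dwells = np.array(dwells)
        dists = np.array(dists)
        assert dwells.min() >= 2.0 and dwells.max() <= 4.0
        assert dwells.mean() == pytest.approx(3.0, abs=0.05)
        assert dists.min() >= 2.0 and dists.max() <= 6.0

    def test_bonus_awarded_after_dwell_inside_radius(self):
        spec = TargetSpec(index=1, location=np.zeros(2), required_dwell=2.5)
        pos = np.array([0.29, 0.0])
        total = 0.0
        for _ in range(260):
            bonus, spec, advance = update_target(spec, pos, DT, CFG)
            total += bonus
        assert total == 500.0
        assert spec.awarded and advance is False  # advance was one-shot

    def test_no_bonus_outside_radius(self):
        spec = TargetSpec(index=1, location=np.zeros(2), required_dwell=2.0)
        pos = np.array([0.31, 0.0])
        for _ in range(2000):
            bonus, spec, _ = update_target(spec, pos, DT, CFG)
            assert bonus == 0.0
        assert not spec.awarded

    def test_dwell_clock_resets_on_leaving(self):
        spec = TargetSpec(index=1, location=np.zeros(2), required_dwell=2.0)
        inside = np.array([0.2, 0.0])
        outside = np.array([0.5, 0.0])
        for _ in range(190):  # 1.9 s inside
            update_target(spec, inside, DT, CFG)
        assert spec.dwell_accrued == pytest.approx(1.9)
        update_target(spec, outside, DT, CFG)
        assert spec.dwell_accrued == 0.0


class TestVelocityField:
    def test_magnitude_and_direction(self):
        f = VelocityField(target=np.array([10.0, 0.0]), speed=1.4)
        v = f.velocity_at(np.zeros(2))
        assert v == pytest.approx([1.4, 0.0])

    def test_taper_inside_proximity_radius(self):
        f = VelocityField(target=np.zeros(2), speed=1.4)
        v = f.velocity_at(np.array([-0.15, 0.0]))
        assert np.linalg.norm(v) == pytest.approx(1.4 * 0.15 / 0.3)
        assert np.linalg.norm(f.velocity_at(np.zeros(2))) == 0.0

    def test_local_map_shape_and_uniformity(self):
        f = VelocityField(target=np.array([1000.0, 0.0]), speed=1.4)
        m = f.local_map(np.zeros(2), heading=0.0)
        assert m.shape == (242,)
        assert np.allclose(m[:121], 1.4, atol=0.01)   # forward components
        assert np.allclose(m[121:], 0.0, atol=0.01)   # lateral components

    def test_map_center_cell_is_v_tgt0(self):
        f = VelocityField(target=np.array([3.0, 1.0]), speed=1.4)
        pel = np.array([1.0, 0.5])
        m = f.local_map(pel, heading=0.0)
        center = 121 // 2
        v = f.velocity_at(pel)
        assert m[center] == pytest.approx(v[0])
        assert m[121 + center] == pytest.approx(v[1])

    def test_map_zero_at_target(self):
        f = VelocityField(target=np.zeros(2), speed=1.4)
        m = f.local_map(np.zeros(2))
        center = 121 // 2
        assert m[center] == 0.0 and m[121 + center] == 0.0


class TestEpisodeResult:
    def test_decomposition_enforced(self):
        r = total_reward(10.0, 20.0, 500.0)
        assert r.J == pytest.approx(530.0, abs=1e-12)
        with pytest.raises(ValueError):
            EpisodeResult(J=100.0, R_alive=10.0, R_step=20.0, R_target=500.0)


class TestScorerProperties:
    def _run(self, n, contacts, v_pel, v_tgt_far=True, acts=None):
        cfg = RewardConfig()
        targets = [TargetSpec(index=1, location=np.array([1e4, 0.0]),
                              required_dwell=2.0)]
        sc = TaskScorer(cfg, targets=targets)
        sc.start(np.zeros(2))
        acts = np.zeros(22) if acts is None else acts
        for i in range(n):
            sc.step(pelvis_xy=np.zeros(2), v_pel=v_pel(i),
                    foot_contact=contacts(i), activations=acts)
        return sc.finish()

    def test_segmentation_invariance_for_zero_cost(self, rng):
        """Sum of w_s*b_s over any partition of the same duration is equal."""
        cfg = RewardConfig()
        v = np.array([1.4, 0.0])

        def run(boundaries):
            sc = TaskScorer(cfg, targets=[TargetSpec(
                index=1, location=np.array([1e4, 0.0]), required_dwell=2.0)])
            sc.start(np.zeros(2))
            for i in range(300):
                # swing the right foot for 6 steps before each boundary
                in_swing = any(b - 6 <= i < b for b in boundaries)
                sc.step(np.zeros(2), v_pel=sc.v_tgt0(np.zeros(2)),
                        foot_contact=np.array([not in_swing, True]),
                        activations=np.zeros(22))
            return sc.finish().R_step

        results = []
        for _ in range(5):
            nb = rng.integers(1, 6)
            bounds = sorted(rng.choice(np.arange(20, 295, 10), nb,
                                       replace=False))
            results.append(run(list(bounds)))
        assert np.allclose(results, results[0], atol=1e-9)
        assert results[0] == pytest.approx(10.0 * 3.0, abs=1e-9)

    def test_higher_activation_never_increases_reward(self, rng):
        base = rng.uniform(0, 0.5, 22)
        contacts = lambda i: np.array([True, True])
        v = lambda i: np.array([0.0, 0.0])
        res_lo = self._run(200, contacts, v, acts=base)
        res_hi = self._run(200, contacts, v, acts=base + 0.3)
        assert res_hi.J <= res_lo.J

    def test_reward_trace_sums_to_J(self, rng):
        contacts = lambda i: np.array([i % 70 > 8, True])
        v = lambda i: np.array([1.0 + 0.1 * np.sin(i), 0.0])
        res = self._run(250, contacts, v)
        assert res.r_trace.sum() == pytest.approx(res.J, abs=1e-9)
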