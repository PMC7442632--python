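import math

import pytest

from conftest import primed_session, scripted

from panworld.agent_policies import Action, StationaryPolicy, RandomWalkPolicy
from panworld.sim_engine import (
    SessionError,
    move,
    phase_of,
    run_session,
    starting_positions,
    traversal_time,
    update_points,
)
from panworld.world_config import make_treatment_config


def stationary(config):
    return [StationaryPolicy() for _ in range(config.n_avatars)]


class TestClock:
    @pytest.mark.parametrize("t, phase", [
        (0.0, "daylight"), (69.9, "daylight"),
        (70.0, "dusk"), (74.9, "dusk"),
        (75.0, "night"), (89.9, "night"),
    ])
    def test_phases(self, chimp_config, t, phase):
        assert phase_of(chimp_config, t) == phase


class TestMove:
    def test_stationary_keeps_groom_stock(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        before = av.groom_stock
        move(av, (0.0, 0.0), 0.1, chimp_config)
        assert av.groom_stock == before

    def test_clamped_at_west_wall(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        av.x = 0.0
        move(av, (-1.0, 0.0), 0.1, chimp_config)
        assert av.x == 0.0

    def test_depletion_proportional_to_distance(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        av.x, av.y = 3000.0, 5000.0
        start_stock = av.groom_stock = 10.0
        total = 0.0
        for _ in range(100):  # 10 s of walking east
            move(av, (1.0, 0.0), 0.1, chimp_config)
        total = av.cumulative_distance
        assert total == pytest.approx(chimp_config.walk_speed * 10.0)
        assert av.groom_stock == pytest.approx(
            start_stock - chimp_config.groom_walk_depletion * total)


class TestTraversal:
    def test_calibrated_to_twenty_seconds(self, chimp_config):
        assert traversal_time(chimp_config) == pytest.approx(20.0)

    def test_is_22_percent_of_the_day(self, chimp_config):
        frac = traversal_time(chimp_config) / chimp_config.day_length
        assert frac == pytest.approx(0.22, abs=0.005)

    def test_linear_in_speed(self, chimp_config):
        fast = make_treatment_config("chimpanzee",
                                     walk_speed=chimp_config.walk_speed * 2)
        assert traversal_time(fast) == pytest.approx(10.0)


@pytest.fixture(scope="module")
def stationary_log():
    cfg = make_treatment_config("chimpanzee")
    return run_session(cfg, [StationaryPolicy() for _ in range(12)], seed=4)


class TestStationarySession:
    def test_spans_35_days(self, stationary_log):
        log = stationary_log
        assert {ev.day for ev in log.events} == set(range(35))

    def test_two_digestions_per_avatar_per_day(self, stationary_log):
        log = stationary_log
        for aid in range(1, 13):
            n = sum(1 for ev in log.events
                    if ev.type == "digest" and ev.actor == aid)
            assert n == 70

    def test_digestion_floors_at_zero(self, stationary_log):
        log = stationary_log
        # initial stock 5: midday -4 leaves 1, predawn takes only that 1
        day0 = [ev for ev in log.events if ev.type == "digest" and ev.day == 0
                and ev.actor == 1]
        assert day0[0].payload == {"instant": "midday", "lost": 4.0, "stock_after": 1.0}
        assert day0[1].payload == {"instant": "predawn", "lost": 1.0, "stock_after": 0.0}

    def test_timestamps_monotone(self, stationary_log):
        stamps = [(ev.day, ev.t) for ev in stationary_log.events]
        assert stamps == sorted(stamps)


class TestDeterminism:
    def test_identical_runs_identical_logs(self):
        cfg = make_treatment_config("bonobo", n_days=2)
        logs = [run_session(cfg, [RandomWalkPolicy() for _ in range(12)], seed=7)
                for _ in range(2)]
        assert logs[0].events == logs[1].events
        assert logs[0].final_points == logs[1].final_points

    def test_different_seeds_differ(self):
        cfg = make_treatment_config("bonobo", n_days=2)
        a = run_session(cfg, [RandomWalkPolicy() for _ in range(12)], seed=1)
        b = run_session(cfg, [RandomWalkPolicy() for _ in range(12)], seed=2)
        assert a.events != b.events


class TestForageFruit:
    def _at_fruiting_tree(self, config):
        sess = primed_session(config, stationary(config))
        tid = sess.assignment.fruiting_trees["north"][0]
        tree = sess.trees_by_id[tid]
        av = sess.avatars[0]
        av.x, av.y = tree.x, tree.y
        return sess, av, tid

    def test_full_stock_still_consumes_fruit(self, chimp_config):
        sess, av, tid = self._at_fruiting_tree(chimp_config)
        av.food_stock = 10.0
        before = sess.fruit_remaining[tid]
        sess.execute(av, Action.forage_tree(tid), "daylight")
        assert av.food_stock == 10.0
        assert sess.fruit_remaining[tid] == before - 1  # the fruit is gone anyway

    def test_empty_tree_no_event(self, chimp_config):
        sess, av, tid = self._at_fruiting_tree(chimp_config)
        sess.fruit_remaining[tid] = 0
        sess.execute(av, Action.forage_tree(tid), "daylight")
        assert not [e for e in sess.events if e.type == "forage_fruit"]

    def test_handle_time_cooldown(self, chimp_config):
        sess, av, tid = self._at_fruiting_tree(chimp_config)
        av.food_stock = 0.0
        sess.abs_t = 0.0
        sess.execute(av, Action.forage_tree(tid), "daylight")
        sess.abs_t = 0.5  # only half the handling time has elapsed
        sess.execute(av, Action.forage_tree(tid), "daylight")
        assert av.food_stock == 1.0
        sess.abs_t = 1.0
        sess.execute(av, Action.forage_tree(tid), "daylight")
        assert av.food_stock == 2.0

    def test_out_of_range_rejected(self, chimp_config):
        sess, av, tid = self._at_fruiting_tree(chimp_config)
        av.x += chimp_config.interaction_range + 1
        sess.execute(av, Action.forage_tree(tid), "daylight")
        assert not [e for e in sess.events if e.type == "forage_fruit"]

    def test_night_rejected(self, chimp_config):
        sess, av, tid = self._at_fruiting_tree(chimp_config)
        sess.execute(av, Action.forage_tree(tid), "night")
        assert not [e for e in sess.events if e.type == "forage_fruit"]


class TestGraze:
    def _at_patch(self, config):
        sess = primed_session(config, stationary(config))
        gx, gy = sess.grass[0]
        av = sess.avatars[0]
        av.x, av.y = gx, gy
        av.food_stock = 0.0
        return sess, av

    def test_unit_takes_ten_handle_times_in_chimpanzee(self, chimp_config):
        sess, av = self._at_patch(chimp_config)
        for _ in range(99):
            sess.execute(av, Action.graze(0), "daylight")
        assert av.food_stock == 0.0
        sess.execute(av, Action.graze(0), "daylight")  # 100th tick = 10.0 s
        assert av.food_stock == 1.0

    def test_unit_interval_at_least_multiplier_in_bonobo(self, bonobo_config):
        sess, av = self._at_patch(bonobo_config)
        ticks = 0
        while av.food_stock == 0.0:
            sess.execute(av, Action.graze(0), "daylight")
            ticks += 1
        assert ticks * bonobo_config.tick_length >= 3.33

    def test_two_avatars_share_a_patch_at_full_rate(self, chimp_config):
        sess, av = self._at_patch(chimp_config)
        other = sess.avatars[1]
        other.x, other.y = av.x, av.y
        other.food_stock = 0.0
        for _ in range(100):
            sess.execute(av, Action.graze(0), "daylight")
            sess.execute(other, Action.graze(0), "daylight")
        assert av.food_stock == 1.0 and other.food_stock == 1.0

    def test_progress_resets_on_leaving(self, chimp_config):
        sess, av = self._at_patch(chimp_config)
        for _ in range(60):
            sess.execute(av, Action.graze(0), "daylight")
        sess.execute(av, Action.idle(), "daylight")  # interruption
        for _ in range(60):
            sess.execute(av, Action.graze(0), "daylight")
        assert av.food_stock == 0.0  # partial units are not banked


class TestGroom:
    def _pair(self, config):
        sess = primed_session(config, stationary(config))
        a, b = sess.avatars[0], sess.avatars[1]
        b.x, b.y = a.x, a.y
        return sess, a, b

    def test_groom_increments_target(self, chimp_config):
        sess, a, b = self._pair(chimp_config)
        b.groom_stock = 3.0
        sess.execute(a, Action.groom(b.id), "daylight")
        assert b.groom_stock == 4.0
        assert [e for e in sess.events if e.type == "groom"]

    def test_cooldown_rejects_early_repeat(self, chimp_config):
        sess, a, b = self._pair(chimp_config)
        b.groom_stock = 0.0
        sess.abs_t = 0.0
        sess.execute(a, Action.groom(b.id), "daylight")
        sess.abs_t = 2.0
        sess.execute(a, Action.groom(b.id), "daylight")
        assert b.groom_stock == 1.0
        sess.abs_t = 4.0
        sess.execute(a, Action.groom(b.id), "daylight")
        assert b.groom_stock == 2.0

    def test_self_groom_rejected(self, chimp_config):
        sess, a, _ = self._pair(chimp_config)
        a.groom_stock = 0.0
        sess.execute(a, Action.groom(a.id), "daylight")
        assert a.groom_stock == 0.0
        assert not [e for e in sess.events if e.type == "groom"]

    def test_cap_recorded_but_not_exceeded(self, chimp_config):
        sess, a, b = self._pair(chimp_config)
        b.groom_stock = 10.0
        sess.execute(a, Action.groom(b.id), "daylight")
        assert b.groom_stock == 10.0
        assert [e for e in sess.events if e.type == "groom"]


class TestPoints:
    def test_full_night_of_nesting(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        av.nested = True
        av.food_stock = av.groom_stock = 5.0  # neutral band
        av.points = 0.0
        for _ in range(150):  # 15 s of night
            update_points(av, "night", 0.1, chimp_config)
        assert av.points == pytest.approx(0.3 * 15)

    def test_neutral_band_inclusive(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        av.points = 50.0
        for stocks in [(4.0, 7.0), (7.0, 4.0), (5.5, 5.5)]:
            av.food_stock, av.groom_stock = stocks
            update_points(av, "daylight", 0.1, chimp_config)
        assert av.points == 50.0

    def test_gain_and_loss_rates(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        av.points = 50.0
        av.food_stock, av.groom_stock = 8.0, 8.0
        update_points(av, "daylight", 1.0, chimp_config)
        assert av.points == pytest.approx(50.0 + 2 * 0.1)
        av.food_stock, av.groom_stock = 3.0, 3.0
        update_points(av, "daylight", 1.0, chimp_config)
        assert av.points == pytest.approx(50.0 + 0.2 - 0.2)

    def test_capped_at_100(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        av.points, av.food_stock, av.groom_stock = 100.0, 10.0, 10.0
        update_points(av, "daylight", 1.0, chimp_config)
        assert av.points == 100.0

    def test_awake_at_night_earns_nothing(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        av.points, av.food_stock, av.groom_stock = 50.0, 10.0, 0.0
        update_points(av, "night", 1.0, chimp_config)
        assert av.points == 50.0


class TestNest:
    def test_accepted_at_night(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        sess.t = 76.0
        sess.execute(av, Action.nest(), "night")
        assert av.nested
        assert [e for e in sess.events if e.type == "nest_start"]

    def test_rejected_in_daylight(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        av = sess.avatars[0]
        sess.t = 60.0
        sess.execute(av, Action.nest(), "daylight")
        assert not av.nested
        assert not [e for e in sess.events if e.type == "nest_start"]


class TestCallsAndVision:
    def test_call_radius_and_bearing(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        caller, near, far = sess.avatars[:3]
        caller.x, caller.y = 3000.0, 3000.0
        near.x, near.y = 3000.0, 5100.0   # 2100 px due south of the caller
        far.x, far.y = 3000.0, 5300.0     # 2300 px away
        sess.execute(caller, Action.call(), "daylight")
        sess.pending_calls = sess._calls_this_tick
        obs_near = sess.observe(near, "daylight")
        obs_far = sess.observe(far, "daylight")
        assert len(obs_near.calls) == 1
        bx, by = obs_near.calls[0]
        assert (bx, by) == pytest.approx((0.0, -1.0))  # caller is due north
        assert obs_far.calls == []

    def test_window_closed_bounds(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        a, b, c = sess.avatars[:3]
        a.x, a.y = 3000.0, 5000.0
        b.x, b.y = a.x + chimp_config.view_width / 2, a.y + chimp_config.view_height / 2
        c.x, c.y = a.x + 800.0, a.y  # 800 > half-width 792
        obs = sess.observe(a, "daylight")
        ids = [v[0] for v in obs.avatars]
        assert b.id in ids and c.id not in ids

    def test_map_overlay_lists_all_trees_without_fruit(self, chimp_config):
        sess = primed_session(chimp_config, stationary(chimp_config))
        obs = sess.observe(sess.avatars[0], "daylight")
        assert len(obs.map_trees) == 10
        assert all(len(entry) == 4 for entry in obs.map_trees)  # no fruit field


class TestPolicyContract:
    def test_malformed_action_aborts_naming_avatar(self, chimp_config):
        cfg = make_treatment_config("chimpanzee", n_days=1)
        policies = [StationaryPolicy() for _ in range(11)] + [scripted(lambda o: 42)]
        with pytest.raises(SessionError, match="avatar 12"):
            run_session(cfg, policies, seed=0)

    def test_wrong_policy_count(self, chimp_config):
        with pytest.raises(SessionError, match="12"):
            run_session(chimp_config, [StationaryPolicy()], seed=0)


@pytest.fixture(scope="module", params=[11, 22, 33])
def random_log_and_session(request):
    from panworld.sim_engine import _Session
    cfg = make_treatment_config("chimpanzee", n_days=2)
    sess = _Session(cfg, [RandomWalkPolicy() for _ in range(12)], request.param)
    log = sess.run()
    return log, sess


class TestEngineInvariants:
    """Random policies must never drive the world out of its invariants."""

    def test_stock_and_point_bounds(self, random_log_and_session):
        log, sess = random_log_and_session
        for av in sess.avatars:
            assert 0 <= av.food_stock <= 10
            assert 0 <= av.groom_stock <= 10
            assert 0 <= av.points <= 100
            assert 0 <= av.x <= log.config.world_width
            assert 0 <= av.y <= log.config.world_height

    def test_fruit_conservation_final_day(self, random_log_and_session):
        log, sess = random_log_and_session
        last = log.config.n_days - 1
        eaten = sum(1 for ev in log.events if ev.day == last
                    and ev.type in ("forage_fruit", "pirate_eat"))
        assert eaten + sum(sess.fruit_remaining.values()) == \
            log.config.treatment.fruit_per_day

    def test_night_lockout(self, random_log_and_session):
        log, _ = random_log_and_session
        for ev in log.events:
            if ev.type in ("forage_fruit", "forage_grass_unit", "groom"):
                assert ev.t < 75.0

    def test_timestamps_monotone(self, random_log_and_session):
        log, _ = random_log_and_session
        stamps = [(ev.day, ev.t) for ev in log.events]
        assert stamps == sorted(stamps)


class TestStartingPositions:
    def test_dispersed_beyond_call_radius(self, chimp_config):
        pos = starting_positions(chimp_config)
        assert len(pos) == 12
        dmin = min(math.hypot(a[0] - b[0], a[1] - b[1])
                   for i, a in enumerate(pos) for b in pos[i + 1:])
        assert dmin > chimp_config.call_radius
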