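"""Discrete-tick world engine: movement, foraging, grooming, digestion,
points, calling, nesting, and the pirate, over 35 x 90-second days.

The engine advances in fixed 0.1-s ticks.  Each tick every awake avatar
receives an :class:`~panworld.agent_policies.Observation` limited to its
1584 x 947 px viewing window (plus the tree map and call bearings, matching
the information humans had) and returns exactly one action.  Actions are
executed in ascending avatar id, which is the documented tie-break for
contested resources such as the last fruit on a tree.

Everything is reproducible: one master seed is split into independent named
sub-streams (daily food placement, pirate spawning, pirate eating, and one
per-avatar policy stream), so re-running ``run_session`` with the same
config, policies, and seed yields a byte-identical event log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .outgroup import PirateManager
from .world_config import (
    DailyFoodAssignment,
    WorldConfig,
    assign_daily_food,
    config_fingerprint,
    traversal_trees,
    tree_layout,
)

__all__ = [
    "AvatarState",
    "Clock",
    "Event",
    "SessionLog",
    "SessionError",
    "session_streams",
    "run_session",
    "move",
    "update_points",
    "traversal_time",
    "phase_of",
    "starting_positions",
]

_EPS = 1e-9

EVENT_TYPES = frozenset({
    "forage_fruit", "forage_grass_unit", "groom", "call", "nest_start",
    "digest", "move_summary", "attack", "attack_outcome", "pirate_spawn",
    "pirate_eat", "pirate_flee", "pirate_death", "points_snapshot",
})


class SessionError(RuntimeError):
    """A policy misbehaved or the session state became inconsistent."""


@dataclass
class AvatarState:
    """Per-avatar live state.  Stocks are clamped to [0, stock_cap] and points
    to [0, point_cap] after every mutation."""

    id: int
    x: float
    y: float
    food_stock: float
    groom_stock: float
    points: float
    nested: bool = False
    grazing_patch: int | None = None
    grazing_ticks: int = 0
    last_forage_t: float = -math.inf
    last_groom_t: float = -math.inf
    cumulative_distance: float = 0.0
    day_distance: float = 0.0


@dataclass(frozen=True)
class Clock:
    day: int
    time_of_day: float
    phase: str  # daylight | dusk | night


@dataclass
class Event:
    day: int
    t: float
    type: str
    actor: int | None = None
    target: int | None = None
    x: float | None = None
    y: float | None = None
    payload: dict = field(default_factory=dict)


@dataclass
class SessionLog:
    config: WorldConfig
    fingerprint: str
    seed: int
    events: list[Event]
    final_points: dict[int, float]

    @property
    def earnings_usd(self) -> dict[int, float]:
        """Points convert to dollars at a 1:1 ratio."""
        return dict(self.final_points)


def phase_of(config: WorldConfig, t: float) -> str:
    if t < config.daylight_length - config.dusk_length - _EPS:
        return "daylight"
    if t < config.daylight_length - _EPS:
        return "dusk"
    return "night"


def session_streams(seed: int) -> dict[str, int]:
    """Named sub-seeds derived from the master seed.

    Exposed so that analysis code (and omniscient diagnostic policies) can
    recompute the food schedule of a session without rerunning it.
    """
    state = np.random.SeedSequence(seed).generate_state(4)
    return {
        "food": int(state[0]),
        "pirate_spawn": int(state[1]),
        "pirate_eat": int(state[2]),
        "policy": int(state[3]),
    }


def starting_positions(config: WorldConfig) -> list[tuple[float, float]]:
    """Initial avatar placements: a staggered grid spread over the world.

    Rows are spaced so that no two avatars start within earshot (the call
    radius) or sight of one another -- the session begins fully dispersed and
    any grouping that follows is produced by behavior, not by the start.
    """
    cols = 3
    out = []
    for i in range(config.n_avatars):
        c, r = i % cols, i // cols
        x = config.world_width * (2 * c + 1) / (2 * cols)
        y = config.world_height * (0.13 + 0.25 * r)
        out.append((min(x, config.world_width), min(y, config.world_height)))
    return out


def move(avatar: AvatarState, direction: tuple[float, float], dt: float,
         config: WorldConfig) -> AvatarState:
    """Advance an avatar along ``direction`` for ``dt`` seconds.

    Position is clamped to the world bounds; groom stock depletes in
    proportion to the distance actually covered (standing still is free).
    Returns the same (mutated) object for convenience.
    """
    dx, dy = direction
    norm = math.hypot(dx, dy)
    if norm < _EPS:
        return avatar
    scale = config.walk_speed * dt / norm * min(1.0, norm)
    nx = min(max(avatar.x + dx * scale, 0.0), config.world_width)
    ny = min(max(avatar.y + dy * scale, 0.0), config.world_height)
    dist = math.hypot(nx - avatar.x, ny - avatar.y)
    avatar.x, avatar.y = nx, ny
    avatar.groom_stock = max(0.0, avatar.groom_stock - config.groom_walk_depletion * dist)
    avatar.cumulative_distance += dist
    avatar.day_distance += dist
    return avatar


def update_points(avatar: AvatarState, phase: str, dt: float, config: WorldConfig) -> AvatarState:
    """Per-tick point accrual from the two stock economies and nesting.

    Stocks strictly below 4 units drain points, strictly above 7 accrue them;
    the band [4, 7] is neutral (inclusive on both ends).  A nested avatar adds
    the nesting rate on top; an avatar awake at night earns and loses nothing.
    """
    if phase == "night" and not avatar.nested:
        return avatar
    delta = 0.0
    for stock in (avatar.food_stock, avatar.groom_stock):
        if stock < config.low_threshold - _EPS:
            delta -= config.point_loss_rate * dt
        elif stock > config.high_threshold + _EPS:
            delta += config.point_gain_rate * dt
    if avatar.nested:
        delta += config.nest_rate * dt
    avatar.points = min(max(avatar.points + delta, 0.0), config.point_cap)
    return avatar


def traversal_time(config: WorldConfig) -> float:
    """Seconds to walk from the southernmost northern tree to the northernmost
    southern tree at the configured speed (calibrated to 20 s by default)."""
    a, b = traversal_trees(config)
    return math.hypot(a.x - b.x, a.y - b.y) / config.walk_speed


class _Session:
    """Internal mutable world; one instance per run_session call."""

    def __init__(self, config: WorldConfig, policies, seed: int):
        self.config = config
        n = config.n_avatars
        if len(policies) != n:
            raise SessionError(f"exactly {n} policies required, got {len(policies)}")
        self.policies = list(policies)
        self.seed = seed
        streams = session_streams(seed)
        self.food_seed = streams["food"]
        self.pirates = PirateManager(
            config,
            spawn_rng=np.random.default_rng(streams["pirate_spawn"]),
            eat_rng=np.random.default_rng(streams["pirate_eat"]),
        )
        policy_root = np.random.SeedSequence(streams["policy"])
        for avatar_id, (policy, child) in enumerate(
                zip(self.policies, policy_root.spawn(n)), start=1):
            policy.reset(avatar_id, np.random.default_rng(child))
        self.trees = tree_layout(config)
        self.trees_by_id = {t.id: t for t in self.trees}
        self.avatars = [
            AvatarState(id=i + 1, x=pos[0], y=pos[1],
                        food_stock=config.initial_stock,
                        groom_stock=config.initial_stock,
                        points=config.initial_points)
            for i, pos in enumerate(starting_positions(config))
        ]
        self.avatars_by_id = {a.id: a for a in self.avatars}
        self.events: list[Event] = []
        self.messages: list[dict] = []
        self.pending_calls: list[tuple[int, float, float]] = []
        self.day = 0
        self.t = 0.0
        self.abs_t = 0.0
        self.assignment: DailyFoodAssignment | None = None
        self.fruit_remaining: dict[int, int] = {}
        self.grass: list[tuple[float, float]] = []
        grass_unit = (config.treatment.grass_time_multiplier
                      * config.treatment.fruit_handle_time)
        self._grass_unit_ticks = max(1, math.ceil(grass_unit / config.tick_length - _EPS))
        self._map_trees = [(t.id, t.grove, t.x, t.y) for t in self.trees]
        self._calls_this_tick: list[tuple[int, float, float]] = []

    def start_day(self, day: int) -> None:
        """Prime the world for one day: food assignment, avatar wake-up,
        pirate schedule."""
        self.day = day
        self.assignment = assign_daily_food(self.config, day, self.food_seed)
        self.fruit_remaining = dict(self.assignment.fruit_on_tree)
        self.grass = self.assignment.grass_patch_locations
        for a in self.avatars:
            a.nested = False
            a.grazing_patch = None
            a.grazing_ticks = 0
            a.day_distance = 0.0
        self.pirates.start_day(self.assignment)

    # -- event plumbing ----------------------------------------------------

    def emit(self, type: str, actor=None, target=None, x=None, y=None, payload=None):
        self.events.append(Event(day=self.day, t=round(self.t, 6), type=type,
                                 actor=actor, target=target, x=x, y=y,
                                 payload=payload or {}))

    def post_message(self, text: str, x: float, y: float) -> None:
        self.messages.append({"text": text, "x": x, "y": y,
                              "expires": self.abs_t + self.config.message_display})

    # -- observations --------------------------------------------------------

    def observe(self, avatar: AvatarState, phase: str):
        from .agent_policies import Observation  # local import avoids a cycle

        cfg = self.config
        hw, hh = cfg.view_width / 2.0, cfg.view_height / 2.0
        ax, ay = avatar.x, avatar.y

        def in_window(x, y):
            return abs(x - ax) <= hw + _EPS and abs(y - ay) <= hh + _EPS

        avatars = [(a.id, a.x, a.y, a.nested) for a in self.avatars
                   if a.id != avatar.id and in_window(a.x, a.y)]
        trees = [(tr.id, tr.grove, tr.x, tr.y, self.fruit_remaining.get(tr.id, 0),
                  self.assignment.flower_display.get(tr.id, 0))
                 for tr in self.trees if in_window(tr.x, tr.y)]
        grass = [(i, gx, gy) for i, (gx, gy) in enumerate(self.grass)
                 if in_window(gx, gy)]
        p = self.pirates.visible_state(phase)
        pirates = [(p.index, p.x, p.y, p.status)] if p is not None and in_window(p.x, p.y) else []
        messages = [m["text"] for m in self.messages if in_window(m["x"], m["y"])]
        calls = []
        for caller_id, cx, cy in self.pending_calls:
            if caller_id == avatar.id:
                continue
            d = math.hypot(cx - ax, cy - ay)
            if _EPS < d <= cfg.call_radius:
                calls.append(((cx - ax) / d, (cy - ay) / d))
        return Observation(
            day=self.day, t=self.t, abs_t=self.abs_t, phase=phase, config=cfg,
            self_id=avatar.id, x=ax, y=ay,
            food_stock=avatar.food_stock, groom_stock=avatar.groom_stock,
            points=avatar.points, nested=avatar.nested,
            avatars=avatars, trees=trees, grass=grass, pirates=pirates,
            messages=messages,
            map_trees=self._map_trees, calls=calls,
        )

    # -- action execution ----------------------------------------------------

    def execute(self, avatar: AvatarState, action, phase: str) -> None:
        cfg = self.config
        kind = action.kind
        keeps_grazing = kind == "forage" and action.grass is not None
        if not keeps_grazing:
            avatar.grazing_patch = None
            avatar.grazing_ticks = 0

        if kind == "idle":
            return
        if kind == "move":
            move(avatar, action.direction, cfg.tick_length, cfg)
            return
        if kind == "call":
            self.emit("call", actor=avatar.id, x=avatar.x, y=avatar.y)
            self._calls_this_tick.append((avatar.id, avatar.x, avatar.y))
            return
        if kind == "nest":
            if phase == "night":
                avatar.nested = True
                self.emit("nest_start", actor=avatar.id, x=avatar.x, y=avatar.y)
            return
        if kind == "groom":
            target = self.avatars_by_id.get(action.avatar)
            if (target is None or target.id == avatar.id or phase == "night"
                    or target.nested
                    or self.abs_t - avatar.last_groom_t < cfg.groom_cooldown - _EPS
                    or math.hypot(target.x - avatar.x, target.y - avatar.y)
                    > cfg.interaction_range):
                return
            target.groom_stock = min(cfg.stock_cap, target.groom_stock + 1.0)
            avatar.last_groom_t = self.abs_t
            self.emit("groom", actor=avatar.id, target=target.id,
                      x=avatar.x, y=avatar.y,
                      payload={"target_stock_after": target.groom_stock})
            return
        if kind == "attack":
            self.pirates.try_attack(avatar, self.abs_t, self.emit)
            return
        if kind == "forage":
            if phase == "night":
                return
            if action.tree is not None:
                self._forage_fruit(avatar, action.tree)
            elif action.grass is not None:
                self._graze(avatar, action.grass)
            return
        raise SessionError(f"unknown action kind {kind!r}")

    def _forage_fruit(self, avatar: AvatarState, tid: int) -> None:
        cfg = self.config
        tree = self.trees_by_id.get(tid)
        if tree is None or self.fruit_remaining.get(tid, 0) <= 0:
            return
        if math.hypot(tree.x - avatar.x, tree.y - avatar.y) > cfg.interaction_range:
            return
        if self.abs_t - avatar.last_forage_t < cfg.treatment.fruit_handle_time - _EPS:
            return
        self.fruit_remaining[tid] -= 1
        before = avatar.food_stock
        avatar.food_stock = min(cfg.stock_cap, avatar.food_stock + 1.0)
        avatar.last_forage_t = self.abs_t
        self.emit("forage_fruit", actor=avatar.id, target=tid,
                  x=avatar.x, y=avatar.y,
                  payload={"stock_before": before, "stock_after": avatar.food_stock,
                           "tree_remaining": self.fruit_remaining[tid]})

    def _graze(self, avatar: AvatarState, pid: int) -> None:
        cfg = self.config
        if not 0 <= pid < len(self.grass):
            avatar.grazing_patch = None
            avatar.grazing_ticks = 0
            return
        gx, gy = self.grass[pid]
        if math.hypot(gx - avatar.x, gy - avatar.y) > cfg.interaction_range:
            avatar.grazing_patch = None
            avatar.grazing_ticks = 0
            return
        if avatar.grazing_patch != pid:
            avatar.grazing_patch = pid
            avatar.grazing_ticks = 0
        avatar.grazing_ticks += 1
        if avatar.grazing_ticks >= self._grass_unit_ticks:
            avatar.grazing_ticks -= self._grass_unit_ticks
            before = avatar.food_stock
            avatar.food_stock = min(cfg.stock_cap, avatar.food_stock + 1.0)
            self.emit("forage_grass_unit", actor=avatar.id, target=pid,
                      x=avatar.x, y=avatar.y,
                      payload={"stock_before": before,
                               "stock_after": avatar.food_stock})

    # -- main loop -----------------------------------------------------------

    def run(self) -> SessionLog:
        cfg = self.config
        dt = cfg.tick_length
        ticks_per_day = round(cfg.day_length / dt)
        dusk_start = round((cfg.daylight_length - cfg.dusk_length) / dt)
        night_start = round(cfg.daylight_length / dt)
        midday_tick = round(cfg.daylight_length / 2.0 / dt)
        predawn_tick = ticks_per_day - 1

        for day in range(cfg.n_days):
            self.start_day(day)

            day_base = day * cfg.day_length
            for tick in range(ticks_per_day):
                self.t = tick * dt
                self.abs_t = day_base + self.t
                phase = ("daylight" if tick < dusk_start
                         else "dusk" if tick < night_start else "night")
                if tick == night_start:
                    self.pirates.nightfall(self.t, self.emit)
                self.pirates.maybe_spawn(self.t, self.assignment,
                                         self.trees_by_id, self.emit)
                self._calls_this_tick = []
                for avatar, policy in zip(self.avatars, self.policies):
                    if avatar.nested:
                        continue
                    obs = self.observe(avatar, phase) if policy.needs_observation else None
                    try:
                        action = policy.decide(obs)
                    except Exception as exc:  # noqa: BLE001 - report and abort
                        raise SessionError(
                            f"policy for avatar {avatar.id} raised at day {day} "
                            f"t={self.t:.1f}: {exc!r}") from exc
                    if action is None or not hasattr(action, "kind"):
                        raise SessionError(
                            f"policy for avatar {avatar.id} returned malformed "
                            f"action at day {day} t={self.t:.1f}: {action!r}")
                    self.execute(avatar, action, phase)
                self.pending_calls = self._calls_this_tick
                self.pirates.step_eat(self.t, phase, self.fruit_remaining, self.emit)
                self.pirates.resolve(self.abs_t, self.avatars_by_id, self.emit,
                                     self.post_message)
                if tick == midday_tick or tick == predawn_tick:
                    which = "midday" if tick == midday_tick else "predawn"
                    amount = cfg.digest_midday if which == "midday" else cfg.digest_predawn
                    for a in self.avatars:
                        lost = min(a.food_stock, float(amount))
                        a.food_stock -= lost
                        self.emit("digest", actor=a.id, x=a.x, y=a.y,
                                  payload={"instant": which, "lost": lost,
                                           "stock_after": a.food_stock})
                for a in self.avatars:
                    update_points(a, phase, dt, cfg)
                if self.messages:
                    self.messages = [m for m in self.messages
                                     if m["expires"] > self.abs_t + _EPS]

            self.t = (ticks_per_day - 1) * dt
            self.abs_t = day_base + self.t
            self.pirates.void_pending(self.abs_t, self.emit)
            self.pirates.end_day()
            for a in self.avatars:
                self.emit("move_summary", actor=a.id, x=a.x, y=a.y,
                          payload={"distance": a.day_distance,
                                   "cumulative": a.cumulative_distance})
                self.emit("points_snapshot", actor=a.id, x=a.x, y=a.y,
                          payload={"points": a.points})
            self.pending_calls = []

        return SessionLog(
            config=cfg,
            fingerprint=config_fingerprint(cfg),
            seed=self.seed,
            events=self.events,
            final_points={a.id: a.points for a in self.avatars},
        )


def run_session(config: WorldConfig, policies, seed: int) -> SessionLog:
    """Simulate a full session and return its complete event log.

    ``policies`` must supply exactly ``config.n_avatars`` policy objects (see
    :mod:`panworld.agent_policies`); avatar ids 1..n map to list order.
    """
    return _Session(config, policies, seed).run()
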