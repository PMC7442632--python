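"""Pirate (outgroup competitor) lifecycle and coalition attack resolution.

One pirate per day appears at the largest fruit-bearing tree of a randomly
chosen grove and eats fruit (never grass) at stochastic intervals with a 4-s
mean.  Residents may attack it at a 10-point stake; a beam links attacker and
pirate for 10 s, and the outcome depends on how many beams overlap:

* a beam that expires having never overlapped another costs its attacker 10
  points (the pirate keeps eating);
* two overlapping beams scare the pirate away for the rest of the day at no
  cost to either attacker;
* the instant three or more beams are concurrently active the pirate is
  killed and never returns.  There are only three pirates per world; after
  the third kill none ever spawn again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .world_config import DailyFoodAssignment, WorldConfig, largest_fruiting_tree

__all__ = [
    "PirateState",
    "AttackBeam",
    "PirateManager",
    "MSG_TWO_ATTACKERS",
    "MSG_THREE_ATTACKERS",
    "pirate_label",
    "simulate_eat_intervals",
]

MSG_TWO_ATTACKERS = (
    "Pirates will be scared away if 2 avatars attack it simultaneously, "
    "and you will incur no damage."
)
MSG_THREE_ATTACKERS = (
    "3 simultaneous attackers will kill this pirate, and you will incur no damage."
)


def pirate_label(index: int) -> str:
    return f"{index} of 3 pirates"


@dataclass
class PirateState:
    index: int  # 1..3
    status: str = "absent"  # absent | present | fled | dead
    x: float = 0.0
    y: float = 0.0
    spawn_tree: int | None = None
    next_eat_time: float = math.inf
    first_appearance: bool = True


@dataclass
class AttackBeam:
    attacker: int
    pirate_index: int
    start_time: float
    expiry: float
    max_concurrency: int = 1


def _draw_interval(config: WorldConfig, rng: np.random.Generator) -> float:
    if config.pirate_eat_law == "fixed":
        return config.pirate_eat_mean_interval
    return float(rng.exponential(config.pirate_eat_mean_interval))


def simulate_eat_intervals(config: WorldConfig, n: int, seed: int) -> np.ndarray:
    """Inter-eat intervals of the pirate feeding process at an always-stocked
    tree, drawn through the same law the engine schedules eats with."""
    rng = np.random.default_rng(seed)
    return np.array([_draw_interval(config, rng) for _ in range(n)])


class PirateManager:
    """Owns pirate state, the spawn/eat schedules, and beam resolution.

    The engine drives it once per tick; events are emitted through the
    engine-supplied callback so ordering and timestamps stay centralized.
    """

    def __init__(self, config: WorldConfig, spawn_rng: np.random.Generator,
                 eat_rng: np.random.Generator):
        self.config = config
        self.spawn_rng = spawn_rng
        self.eat_rng = eat_rng
        self.kills = 0
        self.pirate: PirateState | None = None
        self.beams: list[AttackBeam] = []
        self._spawn_time: float | None = None
        self._spawn_tree: int | None = None
        self._corpse_visible = False

    # -- daily lifecycle ---------------------------------------------------

    def start_day(self, assignment: DailyFoodAssignment) -> None:
        """Schedule today's pirate: random grove, uniform daylight spawn time.

        The random draws happen every day (even after the third kill) so the
        environment stream is identical whether or not pirates remain; only
        the spawn itself is suppressed.
        """
        self.beams = []
        self._corpse_visible = False
        grove = "north" if self.spawn_rng.random() < 0.5 else "south"
        t = float(self.spawn_rng.uniform(0.0, self.config.daylight_length - self.config.dusk_length))
        if self.kills >= self.config.n_pirates:
            self.pirate = None
            self._spawn_time = None
            return
        self._spawn_time = t
        self._spawn_tree = None
        index = self.kills + 1
        first = self.pirate is None or self.pirate.index != index
        self.pirate = PirateState(index=index, first_appearance=first)
        self._grove = grove

    def maybe_spawn(self, t: float, assignment: DailyFoodAssignment, trees_by_id,
                    emit) -> None:
        p = self.pirate
        if p is None or p.status != "absent" or self._spawn_time is None:
            return
        if t + 1e-9 < self._spawn_time:
            return
        tid = largest_fruiting_tree(assignment, self._grove)
        tree = trees_by_id[tid]
        p.status = "present"
        p.x, p.y = tree.x, tree.y
        p.spawn_tree = tid
        p.next_eat_time = t + _draw_interval(self.config, self.eat_rng)
        emit("pirate_spawn", actor=None, target=None, x=p.x, y=p.y,
             payload={"index": p.index, "tree": tid, "grove": self._grove,
                      "label": pirate_label(p.index)})
        p.first_appearance = False

    def end_day(self) -> None:
        """Day rollover: a surviving pirate departs; pending beams were already
        voided at the last tick."""
        if self.pirate is not None and self.pirate.status in ("present", "fled"):
            self.pirate.status = "absent"

    def nightfall(self, t: float, emit) -> None:
        """At night the corpse disappears and any still-pending beams on a
        live pirate keep running (the pirate stays until the day ends)."""
        self._corpse_visible = False

    # -- eating ------------------------------------------------------------

    def step_eat(self, t: float, phase: str, fruit_remaining: dict[int, int], emit) -> None:
        p = self.pirate
        if p is None or p.status != "present" or phase == "night":
            return
        while t + 1e-9 >= p.next_eat_time:
            if fruit_remaining.get(p.spawn_tree, 0) <= 0:
                return  # tree empty: the pirate idles in place
            fruit_remaining[p.spawn_tree] -= 1
            emit("pirate_eat", actor=None, target=None, x=p.x, y=p.y,
                 payload={"index": p.index, "tree": p.spawn_tree,
                          "tree_remaining": fruit_remaining[p.spawn_tree],
                          "scheduled_t": p.next_eat_time})
            p.next_eat_time += _draw_interval(self.config, self.eat_rng)

    # -- attacking ---------------------------------------------------------

    def try_attack(self, avatar, t: float, emit) -> bool:
        """Create a beam if the attack is legal; returns True on success."""
        p = self.pirate
        if p is None or p.status != "present":
            return False
        if avatar.points + 1e-9 < self.config.attack_cost:
            return False
        if math.hypot(avatar.x - p.x, avatar.y - p.y) > self.config.interaction_range:
            return False
        if any(b.attacker == avatar.id for b in self.beams):
            return False  # one live beam per attacker
        beam = AttackBeam(attacker=avatar.id, pirate_index=p.index,
                          start_time=t, expiry=t + self.config.attack_window)
        self.beams.append(beam)
        emit("attack", actor=avatar.id, target=p.index, x=avatar.x, y=avatar.y,
             payload={"start": t})
        return True

    def resolve(self, t: float, avatars_by_id, emit, post_message) -> None:
        """Per-tick beam resolution.  Kill takes precedence over flee."""
        p = self.pirate
        if p is None or not self.beams:
            return
        if p.status != "present":
            self.beams = []
            return
        # every listed beam is live through its expiry tick (closed window),
        # so a third beam landing the tick a pair would flee still kills
        active = self.beams
        n = len(active)
        for b in active:
            if n > b.max_concurrency:
                b.max_concurrency = n
                if n == 2:
                    post_message(MSG_THREE_ATTACKERS, p.x, p.y)
        if n >= 3:
            self.kills += 1
            p.status = "dead"
            self._corpse_visible = True
            emit("attack_outcome", actor=None, target=p.index, x=p.x, y=p.y,
                 payload={"outcome": "kill", "n_attackers": n,
                          "attackers": sorted(b.attacker for b in active)})
            emit("pirate_death", actor=None, target=p.index, x=p.x, y=p.y,
                 payload={"index": p.index, "kills_total": self.kills})
            self.beams = []
            return
        expired = [b for b in self.beams if b.expiry <= t + 1e-9]
        for b in expired:
            if p.status != "present":
                break
            if b.max_concurrency >= 2:
                # the 2-overlap episode ends here: the pirate is scared away
                pair = [x for x in self.beams if x.max_concurrency >= 2]
                p.status = "fled"
                emit("attack_outcome", actor=None, target=p.index, x=p.x, y=p.y,
                     payload={"outcome": "flee", "n_attackers": len(pair),
                              "attackers": sorted(x.attacker for x in pair)})
                emit("pirate_flee", actor=None, target=p.index, x=p.x, y=p.y,
                     payload={"index": p.index})
                self.beams = []
                return
            attacker = avatars_by_id[b.attacker]
            before = attacker.points
            attacker.points = max(0.0, attacker.points - self.config.attack_cost)
            emit("attack_outcome", actor=b.attacker, target=p.index, x=p.x, y=p.y,
                 payload={"outcome": "penalty", "n_attackers": 1,
                          "attackers": [b.attacker],
                          "points_before": before, "points_after": attacker.points})
            post_message(MSG_TWO_ATTACKERS, p.x, p.y)
            self.beams.remove(b)

    def void_pending(self, t: float, emit) -> None:
        """Void beams that are still open when the day ends."""
        p = self.pirate
        if self.beams and p is not None:
            emit("attack_outcome", actor=None, target=p.index, x=p.x, y=p.y,
                 payload={"outcome": "void", "n_attackers": len(self.beams),
                          "attackers": sorted(b.attacker for b in self.beams)})
        self.beams = []

    # -- visibility --------------------------------------------------------

    def visible_state(self, phase: str) -> PirateState | None:
        """The pirate as others can see it (corpse shown until nightfall)."""
        p = self.pirate
        if p is None:
            return None
        if p.status == "present":
            return p
        if p.status == "dead" and self._corpse_visible and phase != "night":
            return p
        return None
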