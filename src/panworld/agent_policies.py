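"""Policy contract and scripted baseline policies.

Policies stand in for the human subjects: they see only an
:class:`Observation` (the avatar's own state, whatever falls inside its
viewing window, the tree map without fruiting state, incoming call bearings,
and any displayed pirate messages — information parity with the original
interface) and return exactly one :class:`Action` per tick.

The scripted policies are demonstrative foragers, not models of human
cognition.  Their tunable constants (satiation targets, herd ranges, attack
coordination rules) are documented class attributes.  Two named profiles act
as the synthetic stand-ins for the behavioral contrast the experiment
produced:

* ``split_grove_frugivores`` — six avatars committed to each grove, greedy
  fruit foraging plus coalition attacking (fission into two subgroups, high
  outgroup aggression).
* ``herd_grazers`` — all twelve follow a grazing/grooming herd that coalesces
  through calls and never attacks (one large cohesive group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sim_engine import SessionLog, run_session, session_streams
from .world_config import (
    WorldConfig,
    assign_daily_food,
    make_treatment_config,
)

__all__ = [
    "Observation",
    "Action",
    "Policy",
    "StationaryPolicy",
    "RandomWalkPolicy",
    "GreedyFrugivore",
    "HerdGrazerGroomer",
    "PirateKiller",
    "SentinelAttacker",
    "OmniscientForager",
    "decide_action",
    "POLICY_REGISTRY",
    "PROFILES",
    "make_profile_policies",
    "generate_fixture_session",
    "policies_from_assignment",
    "estimate_max_daily_intake",
]


@dataclass
class Observation:
    """Everything an avatar may act on at one tick."""

    day: int
    t: float
    abs_t: float  # seconds since session start (cooldown arithmetic spans days)
    phase: str
    config: WorldConfig
    self_id: int
    x: float
    y: float
    food_stock: float
    groom_stock: float
    points: float
    nested: bool
    avatars: list[tuple[int, float, float, bool]]        # (id, x, y, nested)
    trees: list[tuple[int, str, float, float, int, int]]  # (id, grove, x, y, fruit, flowers)
    grass: list[tuple[int, float, float]]                 # (patch id, x, y)
    pirates: list[tuple[int, float, float, str]]          # (index, x, y, status)
    messages: list[str]
    map_trees: list[tuple[int, str, float, float]]        # overlay: locations only
    calls: list[tuple[float, float]]                      # unit bearings to callers


@dataclass
class Action:
    kind: str  # move | forage | groom | call | attack | nest | idle
    direction: tuple[float, float] | None = None
    tree: int | None = None
    grass: int | None = None
    avatar: int | None = None
    pirate: int | None = None

    @staticmethod
    def move(dx: float, dy: float) -> "Action":
        return Action("move", direction=(dx, dy))

    @staticmethod
    def move_toward(obs: Observation, x: float, y: float) -> "Action":
        return Action("move", direction=(x - obs.x, y - obs.y))

    @staticmethod
    def forage_tree(tid: int) -> "Action":
        return Action("forage", tree=tid)

    @staticmethod
    def graze(pid: int) -> "Action":
        return Action("forage", grass=pid)

    @staticmethod
    def groom(aid: int) -> "Action":
        return Action("groom", avatar=aid)

    @staticmethod
    def call() -> "Action":
        return Action("call")

    @staticmethod
    def attack(index: int) -> "Action":
        return Action("attack", pirate=index)

    @staticmethod
    def nest() -> "Action":
        return Action("nest")

    @staticmethod
    def idle() -> "Action":
        return Action("idle")


class Policy:
    """Base policy.  ``reset`` binds the avatar id and a private RNG stream
    (derived from the session seed, independent of environment streams)."""

    needs_observation = True

    def reset(self, avatar_id: int, rng: np.random.Generator) -> None:
        self.avatar_id = avatar_id
        self.rng = rng

    def decide(self, obs: Observation | None) -> Action:
        raise NotImplementedError


def decide_action(policy: Policy, obs: Observation | None) -> Action:
    """Thin functional wrapper over the policy contract."""
    return policy.decide(obs)


def _dist(obs: Observation, x: float, y: float) -> float:
    return math.hypot(x - obs.x, y - obs.y)


def _nearest(obs: Observation, items, xi: int, yi: int):
    return min(items, key=lambda it: _dist(obs, it[xi], it[yi]), default=None) \
        if items else None


class StationaryPolicy(Policy):
    """Does nothing, ever.  Useful as a physics/metabolism control."""

    needs_observation = False

    def decide(self, obs=None) -> Action:
        return Action.idle()


class RandomWalkPolicy(Policy):
    """Uniformly random legal actions; used to property-test engine invariants."""

    def decide(self, obs: Observation) -> Action:
        r = self.rng
        choice = r.integers(0, 7)
        if choice == 0:
            return Action.idle()
        if choice == 1:
            ang = r.uniform(0, 2 * math.pi)
            return Action.move(math.cos(ang), math.sin(ang))
        if choice == 2 and obs.trees:
            return Action.forage_tree(int(obs.trees[r.integers(len(obs.trees))][0]))
        if choice == 3 and obs.grass:
            return Action.graze(int(obs.grass[r.integers(len(obs.grass))][0]))
        if choice == 4 and obs.avatars:
            return Action.groom(int(obs.avatars[r.integers(len(obs.avatars))][0]))
        if choice == 5:
            if obs.pirates and r.random() < 0.5:
                return Action.attack(obs.pirates[0][0])
            return Action.call()
        if choice == 6:
            return Action.nest()
        return Action.idle()


class GreedyFrugivore(Policy):
    """Commits to one grove; forages fruit greedily, grooms allies when sated,
    and joins coalition attacks on a visible pirate.

    The attack rule mirrors the three-attacker kill mechanic: an avatar only
    fires when at least two allies are already within interaction range of the
    pirate, so attacks land as triples whenever three arrive together.
    """

    SATED = 8.0
    ATTACK_MIN_POINTS = 12.0
    GRAZE_FALLBACK = 4.0

    def __init__(self, home_grove: str = "north"):
        self.home_grove = home_grove

    def reset(self, avatar_id, rng):
        super().reset(avatar_id, rng)
        self._patrol = avatar_id % 5
        self._last_attack = -math.inf

    def _home_trees(self, obs: Observation):
        return [t for t in obs.map_trees if t[1] == self.home_grove]

    def decide(self, obs: Observation) -> Action:
        if obs.phase == "night":
            return Action.nest()
        cfg = obs.config
        rng_px = cfg.interaction_range

        live = [p for p in obs.pirates if p[3] == "present"]
        if live and obs.points >= self.ATTACK_MIN_POINTS:
            idx, px, py, _ = live[0]
            d = _dist(obs, px, py)
            allies = sum(1 for a in obs.avatars
                         if math.hypot(a[1] - px, a[2] - py) <= rng_px)
            if d <= rng_px * 0.8:
                if allies >= 2 and obs.abs_t - self._last_attack >= cfg.attack_window:
                    self._last_attack = obs.abs_t
                    return Action.attack(idx)
                return Action.idle()
            return Action.move_toward(obs, px, py)

        if obs.food_stock <= 7.0:
            fruiting = [t for t in obs.trees
                        if t[1] == self.home_grove and t[4] > 0]
            if fruiting:
                t = min(fruiting, key=lambda t: _dist(obs, t[2], t[3]))
                if _dist(obs, t[2], t[3]) <= rng_px * 0.8:
                    return Action.forage_tree(t[0])
                return Action.move_toward(obs, t[2], t[3])
            if obs.food_stock <= self.GRAZE_FALLBACK and obs.grass:
                g = min(obs.grass, key=lambda g: _dist(obs, g[1], g[2]))
                if _dist(obs, g[1], g[2]) <= rng_px * 0.8:
                    return Action.graze(g[0])
                return Action.move_toward(obs, g[1], g[2])
            home = self._home_trees(obs)
            target = home[self._patrol % len(home)]
            if _dist(obs, target[2], target[3]) <= rng_px:
                self._patrol += 1  # tree visited and barren; try the next
                return Action.idle()
            return Action.move_toward(obs, target[2], target[3])

        # sated: drift to the grove center and groom whoever is closest, so
        # the subgroup ends its day (and nests) together
        home = self._home_trees(obs)
        cx = sum(t[2] for t in home) / len(home)
        cy = sum(t[3] for t in home) / len(home)
        if _dist(obs, cx, cy) > 300:
            return Action.move_toward(obs, cx, cy)
        if obs.avatars:
            a = min(obs.avatars, key=lambda a: _dist(obs, a[1], a[2]))
            if _dist(obs, a[1], a[2]) <= rng_px:
                return Action.groom(a[0])
            return Action.move_toward(obs, a[1], a[2])
        return Action.idle()


class HerdGrazerGroomer(Policy):
    """Grazes until sated, grooms and stays with visible companions, and
    recruits others to grass patches with calls.  Never attacks.

    Cohesion is emergent rather than scripted: an avatar never wanders away
    from visible companions (the "leash"), a grazing avatar re-advertises its
    patch with a call between grass units (when grazing progress is at zero,
    so no progress is lost), and hungry avatars follow fresh call bearings.
    Avatars start mutually out of sight, so the herd assembles gradually over
    days through chance encounters and call chains -- the mechanism behind the
    declining nesting-proximity trend this profile demonstrates.
    """

    SATED = 8.0          # graze until food stock reaches this
    LEASH = 250.0        # px: approach the nearest companion beyond this
    DRIFT = 500.0        # px: never let the visible centroid get farther
    CALL_PERIOD = 8.0    # s between lonely calls
    ADVERT_PERIOD = 16.0  # s between herd-location adverts while content
    HEADING_JITTER = 0.15  # rad of personal deviation from the shared heading
    BEARING_FRESH = 5.0  # s a heard call bearing stays worth following

    def reset(self, avatar_id, rng):
        super().reset(avatar_id, rng)
        self._last_call = -1e9
        self._last_groom = -1e9
        self._heading_day = -1
        self._heading = (1.0, 0.0)
        self._last_bearing: tuple[float, float] | None = None
        self._bearing_until = -1e9
        self._gpatch: tuple[int, int] | None = None
        self._gticks = 0

    def _note_calls(self, obs: Observation) -> None:
        """Remember the mean bearing of *external* calls: ones that do not
        point at any visible companion, i.e. come from a caller out of sight.
        Calls from within one's own cluster are already actionable by sight
        and following them blindly would just churn the cluster."""
        external = []
        for bx, by in obs.calls:
            internal = False
            for aid, ax, ay, _nested in obs.avatars:
                dx, dy = ax - obs.x, ay - obs.y
                dn = math.hypot(dx, dy)
                if dn > 1e-9 and (bx * dx + by * dy) / dn > 0.94:  # within ~20 deg
                    internal = True
                    break
            if not internal:
                external.append((bx, by))
        if external:
            bx = sum(c[0] for c in external)
            by = sum(c[1] for c in external)
            n = math.hypot(bx, by)
            if n > 1e-9:
                self._last_bearing = (bx / n, by / n)
                self._bearing_until = obs.abs_t + self.BEARING_FRESH

    def _call(self, obs: Observation) -> Action:
        self._last_call = obs.abs_t
        return Action.call()

    def _migrate(self, obs: Observation) -> Action:
        """March on the day's shared migration heading (a common route all
        herd members derive from the day index, with a little personal
        jitter), so a searching cluster moves as a unit instead of
        diffusing."""
        if self._heading_day != obs.day:
            self._heading_day = obs.day
            ang = (obs.day * 2.399963) % (2 * math.pi) \
                + self.rng.uniform(-self.HEADING_JITTER, self.HEADING_JITTER)
            self._heading = (math.cos(ang), math.sin(ang))
        return Action.move(*self._heading)

    def _search(self, obs: Observation) -> Action:
        """Nothing edible at hand: answer external calls, stay leashed and
        migrate; if alone, advertise for company."""
        if self._last_bearing is not None and obs.abs_t < self._bearing_until:
            return Action.move(*self._last_bearing)
        if obs.avatars:
            a = min(obs.avatars, key=lambda a: _dist(obs, a[1], a[2]))
            if _dist(obs, a[1], a[2]) > self.LEASH:
                return Action.move_toward(obs, a[1], a[2])
            return self._migrate(obs)
        if obs.abs_t - self._last_call >= self.CALL_PERIOD:
            return self._call(obs)
        return self._migrate(obs)

    def decide(self, obs: Observation) -> Action:
        if obs.phase == "night":
            return Action.nest()
        self._note_calls(obs)
        cfg = obs.config
        rng_px = cfg.interaction_range

        if obs.food_stock < self.SATED:
            if obs.grass:
                # consensus patch choice: pick the patch nearest the visible
                # cluster's centroid so the whole herd converges on one patch
                if obs.avatars:
                    cx = (sum(a[1] for a in obs.avatars) + obs.x) / (len(obs.avatars) + 1)
                    cy = (sum(a[2] for a in obs.avatars) + obs.y) / (len(obs.avatars) + 1)
                    g = min(obs.grass,
                            key=lambda g: math.hypot(g[1] - cx, g[2] - cy))
                else:
                    g = min(obs.grass, key=lambda g: _dist(obs, g[1], g[2]))
                if _dist(obs, g[1], g[2]) <= rng_px * 0.8:
                    unit_ticks = math.ceil(
                        cfg.treatment.grass_time_multiplier
                        * cfg.treatment.fruit_handle_time / cfg.tick_length - 1e-9)
                    if self._gpatch != (obs.day, g[0]):
                        self._gpatch = (obs.day, g[0])
                        self._gticks = 0
                        return self._call(obs)  # announce the patch
                    if self._gticks >= unit_ticks:
                        self._gticks = 0  # a unit just completed; re-advertise
                        return self._call(obs)
                    self._gticks += 1
                    return Action.graze(g[0])
                self._gpatch = None
                return Action.move_toward(obs, g[1], g[2])
            self._gpatch = None
            return self._search(obs)

        self._gpatch = None
        if self._last_bearing is not None and obs.abs_t < self._bearing_until:
            return Action.move(*self._last_bearing)
        if obs.avatars:
            a = min(obs.avatars, key=lambda a: _dist(obs, a[1], a[2]))
            d = _dist(obs, a[1], a[2])
            if d <= rng_px and obs.abs_t - self._last_groom >= cfg.groom_cooldown:
                self._last_groom = obs.abs_t
                return Action.groom(a[0])
            if d > self.LEASH:
                return Action.move_toward(obs, a[1], a[2])
            if obs.abs_t - self._last_call >= self.ADVERT_PERIOD:
                return self._call(obs)  # keep advertising the herd's location
            return Action.idle()
        return self._search(obs)


class PirateKiller(Policy):
    """Scripted coalition hunter: waits at a station, converges on calls, and
    fires only when a three-strong party surrounds the pirate.  Used to verify
    the kill ladder and the three-pirates-per-world cap."""

    def __init__(self, station: tuple[float, float]):
        self.station = station

    def reset(self, avatar_id, rng):
        super().reset(avatar_id, rng)
        self._last_attack = -math.inf
        self._last_call = -math.inf
        self._bearing: tuple[float, float] | None = None
        self._bearing_until = -math.inf

    def decide(self, obs: Observation) -> Action:
        if obs.phase == "night":
            return Action.nest()
        cfg = obs.config
        rng_px = cfg.interaction_range
        if obs.calls:
            bx = sum(c[0] for c in obs.calls)
            by = sum(c[1] for c in obs.calls)
            n = math.hypot(bx, by)
            if n > 1e-9:
                self._bearing = (bx / n, by / n)
                self._bearing_until = obs.abs_t + 4.5
        live = [p for p in obs.pirates if p[3] == "present"]
        if live:
            idx, px, py, _ = live[0]
            d = _dist(obs, px, py)
            if d <= rng_px * 0.8:
                allies = sum(1 for a in obs.avatars
                             if math.hypot(a[1] - px, a[2] - py) <= rng_px)
                if (allies >= 2 and obs.points >= cfg.attack_cost
                        and obs.abs_t - self._last_attack >= cfg.attack_window):
                    self._last_attack = obs.abs_t
                    return Action.attack(idx)
                if obs.abs_t - self._last_call >= 4.0:
                    self._last_call = obs.abs_t
                    return Action.call()
                return Action.idle()
            return Action.move_toward(obs, px, py)
        if self._bearing is not None and obs.abs_t < self._bearing_until:
            return Action.move(*self._bearing)
        if _dist(obs, *self.station) > 30:
            return Action.move_toward(obs, *self.station)
        return Action.idle()


class SentinelAttacker(Policy):
    """Camps at a fixed post and launches one solo attack on a pirate that
    appears at that post (pirates elsewhere are ignored, so two sentinels at
    different posts can never accidentally form a coalition).  Used to
    measure the lone-attacker penalty."""

    def __init__(self, station: tuple[float, float], max_attacks: int = 1):
        self.station = station
        self.max_attacks = max_attacks

    def reset(self, avatar_id, rng):
        super().reset(avatar_id, rng)
        self._attacks = 0

    def decide(self, obs: Observation) -> Action:
        if obs.phase == "night":
            return Action.nest()
        live = [p for p in obs.pirates if p[3] == "present"
                and math.hypot(p[1] - self.station[0], p[2] - self.station[1]) <= 200.0]
        if live and self._attacks < self.max_attacks:
            idx, px, py, _ = live[0]
            if _dist(obs, px, py) <= obs.config.interaction_range * 0.8:
                self._attacks += 1
                return Action.attack(idx)
            return Action.move_toward(obs, px, py)
        if _dist(obs, *self.station) > 30:
            return Action.move_toward(obs, *self.station)
        return Action.idle()


class OmniscientForager(Policy):
    """Diagnostic-only greedy forager that recomputes the session's food
    schedule from the (config, seed) pair, so it always knows where fruit is.

    Breaks information parity by design; it exists to measure the maximum
    attainable daily intake of a lone agent (the treatment-parity check), not
    to emulate a subject.
    """

    def __init__(self, config: WorldConfig, session_seed: int):
        self.config = config
        self.food_seed = session_streams(session_seed)["food"]
        self._assignments = {}

    def _assignment(self, day: int):
        if day not in self._assignments:
            self._assignments[day] = assign_daily_food(self.config, day, self.food_seed)
        return self._assignments[day]

    def reset(self, avatar_id, rng):
        super().reset(avatar_id, rng)
        self._eaten: dict[tuple[int, int], int] = {}
        self._last_bite = -1e9

    def decide(self, obs: Observation) -> Action:
        if obs.phase == "night":
            return Action.nest()
        if obs.food_stock >= obs.config.stock_cap:
            return Action.idle()
        asg = self._assignment(obs.day)
        pos = {(t[0]): (t[2], t[3]) for t in obs.map_trees}
        stocked = [(tid, amt - self._eaten.get((obs.day, tid), 0))
                   for tid, amt in asg.fruit_on_tree.items()
                   if amt - self._eaten.get((obs.day, tid), 0) > 0]
        if stocked:
            tid, _ = min(stocked, key=lambda s: _dist(obs, *pos[s[0]]))
            tx, ty = pos[tid]
            if _dist(obs, tx, ty) <= obs.config.interaction_range * 0.8:
                if obs.abs_t - getattr(self, "_last_bite", -1e9) >= obs.config.treatment.fruit_handle_time:
                    self._last_bite = obs.abs_t
                    self._eaten[(obs.day, tid)] = self._eaten.get((obs.day, tid), 0) + 1
                    return Action.forage_tree(tid)
                return Action.idle()
            return Action.move_toward(obs, tx, ty)
        grass = [(i, gx, gy) for i, (gx, gy) in enumerate(asg.grass_patch_locations)]
        g = min(grass, key=lambda g: _dist(obs, g[1], g[2]))
        if _dist(obs, g[1], g[2]) <= obs.config.interaction_range * 0.8:
            return Action.graze(g[0])
        return Action.move_toward(obs, g[1], g[2])


POLICY_REGISTRY = {
    "stationary": StationaryPolicy,
    "random_walk": RandomWalkPolicy,
    "greedy_frugivore": GreedyFrugivore,
    "herd_grazer_groomer": HerdGrazerGroomer,
    "pirate_killer": PirateKiller,
    "sentinel_attacker": SentinelAttacker,
}

PROFILES = ("split_grove_frugivores", "herd_grazers", "mixed")


def make_profile_policies(profile: str, config: WorldConfig) -> list[Policy]:
    """Instantiate the per-avatar policy list for a named profile."""
    n = config.n_avatars
    if profile == "split_grove_frugivores":
        half = n // 2
        return [GreedyFrugivore("north") for _ in range(half)] + \
               [GreedyFrugivore("south") for _ in range(n - half)]
    if profile == "herd_grazers":
        return [HerdGrazerGroomer() for _ in range(n)]
    if profile == "mixed":
        third = n // 4
        return ([GreedyFrugivore("north") for _ in range(third)]
                + [GreedyFrugivore("south") for _ in range(third)]
                + [HerdGrazerGroomer() for _ in range(n - 2 * third)])
    raise ValueError(f"unknown policy profile {profile!r}; valid: {', '.join(PROFILES)}")


def generate_fixture_session(treatment: str, policy_profile: str, seed: int,
                             **config_overrides) -> SessionLog:
    """Run a full synthetic session for a treatment preset and policy profile.

    This is the synthetic stand-in for a human 12-subject session; the
    profiles emulate the qualitative grouping contrast (two grove-bound
    subgroups vs one coalescing herd), not human play.
    """
    config = make_treatment_config(treatment, **config_overrides)
    policies = make_profile_policies(policy_profile, config)
    return run_session(config, policies, seed)


def policies_from_assignment(assignment: dict, config: WorldConfig) -> list[Policy]:
    """Build a policy list from a parsed assignment config.

    Expected shape: ``{"avatars": {"1": {"name": ..., "params": {...}}, ...}}``
    or ``{"profile": "herd_grazers"}``.
    """
    if "profile" in assignment:
        return make_profile_policies(assignment["profile"], config)
    table = assignment.get("avatars")
    if not isinstance(table, dict):
        raise ValueError("policy assignment must contain 'profile' or 'avatars'")
    policies = []
    for i in range(1, config.n_avatars + 1):
        entry = table.get(str(i)) or table.get(i)
        if entry is None:
            raise ValueError(f"no policy assigned to avatar {i}")
        name = entry["name"]
        if name not in POLICY_REGISTRY:
            raise ValueError(f"unknown policy {name!r} for avatar {i}")
        policies.append(POLICY_REGISTRY[name](**entry.get("params", {})))
    return policies


def estimate_max_daily_intake(treatment: str, seed: int, n_days: int = 4) -> list[float]:
    """Per-day food intake of a lone omniscient greedy forager (no pirates).

    Intake counts units actually added to the stock (the cap makes overeating
    worthless), which is the relevant notion of "attainable food": with two
    digestion events of 4 and 7 units, the steady-state attainable intake is
    11 units/day whenever fruit is reachable, in either treatment.
    """
    config = make_treatment_config(treatment, n_avatars=1, n_pirates=0,
                                   n_days=n_days)
    policy = OmniscientForager(config, seed)
    log = run_session(config, [policy], seed)
    intake = [0.0] * n_days
    for ev in log.events:
        if ev.type in ("forage_fruit", "forage_grass_unit"):
            intake[ev.day] += ev.payload["stock_after"] - ev.payload["stock_before"]
    return intake
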