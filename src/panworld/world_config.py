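"""Session parameters, treatment presets, and daily food assignment.

The virtual world is a 6,720 x 10,500 px rectangle with two groves of five
fruit trees each (north and south) and eight grass patches relocated daily.
Two treatment presets differ only in fruit abundance and grass handling time:

* ``chimpanzee`` -- 120 pieces of fruit per day, grazing one food unit takes
  10x the fruit handling time (clumped, high-value food; grass inefficient).
* ``bonobo`` -- 40 pieces of fruit per day, grazing takes 3.33x the fruit
  handling time (dispersed low-value food is a viable staple).

Both presets offer roughly the same aggregate food, because the usable daily
intake is capped by the stock ceiling (10 units) and the two digestion events
(4 units mid-day, 7 pre-dawn).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ConfigError",
    "TreatmentParams",
    "WorldConfig",
    "Tree",
    "DailyFoodAssignment",
    "TREATMENT_PRESETS",
    "make_treatment_config",
    "validate_config",
    "tree_layout",
    "traversal_trees",
    "assign_daily_food",
    "largest_fruiting_tree",
    "load_config",
    "config_fingerprint",
]

#: Calibration constant: walking between the southernmost northern tree and the
#: northernmost southern tree must take this long (22% of the 90-s day).
TRAVERSAL_CALIBRATION_S = 20.0


class ConfigError(ValueError):
    """Raised for invalid or inconsistent world configuration."""


class TreatmentParams(BaseModel):
    """The parameters that differ between the two ecological treatments."""

    model_config = ConfigDict(extra="forbid")

    name: str
    fruit_per_day: int = Field(gt=0)
    #: Time to graze one food unit, relative to handling one piece of fruit.
    grass_time_multiplier: float = Field(gt=1.0)
    #: Seconds to pick one piece of fruit (free constant, not printed anywhere).
    fruit_handle_time: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "TreatmentParams":
        if self.fruit_per_day % 2 != 0:
            raise ValueError(
                "fruit_per_day must be even: fruit is split equally between "
                "the northern and southern groves"
            )
        return self


TREATMENT_PRESETS: dict[str, dict] = {
    "chimpanzee": {"name": "chimpanzee", "fruit_per_day": 120, "grass_time_multiplier": 10.0},
    "bonobo": {"name": "bonobo", "fruit_per_day": 40, "grass_time_multiplier": 3.33},
}


class WorldConfig(BaseModel):
    """All fixed parameters of one 35-day session.

    Geometry is in pixels, the clock in seconds.  Fields whose values the
    source experiment never printed (walking speed, point accrual rates,
    handling times, interaction range, groom depletion per pixel) are exposed
    here with documented defaults rather than treated as facts.
    """

    model_config = ConfigDict(extra="forbid")

    # --- geometry ---
    world_width: float = Field(default=6720.0, gt=0)
    world_height: float = Field(default=10500.0, gt=0)
    view_width: float = Field(default=1584.0, gt=0)
    view_height: float = Field(default=947.0, gt=0)
    call_radius: float = Field(default=2200.0, gt=0)

    # --- clock ---
    day_length: float = Field(default=90.0, gt=0)
    daylight_length: float = Field(default=75.0, gt=0)  # includes dusk
    dusk_length: float = Field(default=5.0, gt=0)
    night_length: float = Field(default=15.0, gt=0)
    n_days: int = Field(default=35, gt=0)
    tick_length: float = Field(default=0.1, gt=0)

    # --- population & food supply ---
    n_avatars: int = Field(default=12, gt=0)
    n_trees_per_grove: int = Field(default=5, gt=0)
    n_fruiting_trees_per_grove: int = Field(default=3, gt=0)
    n_grass_patches: int = Field(default=8, gt=0)

    # --- metabolism & grooming economy ---
    digest_midday: int = Field(default=4, gt=0)
    digest_predawn: int = Field(default=7, gt=0)
    stock_cap: float = Field(default=10.0, gt=0)
    low_threshold: float = Field(default=4.0, gt=0)
    high_threshold: float = Field(default=7.0, gt=0)
    groom_cooldown: float = Field(default=4.0, gt=0)
    groom_walk_depletion: float = Field(default=0.002, ge=0)  # units per pixel

    # --- points ---
    point_cap: float = Field(default=100.0, gt=0)
    nest_rate: float = Field(default=0.3, gt=0)  # points per second while nested
    point_gain_rate: float = Field(default=0.1, gt=0)  # per second per resource
    point_loss_rate: float = Field(default=0.1, gt=0)
    initial_points: float = Field(default=0.0, ge=0)
    initial_stock: float = Field(default=5.0, ge=0)

    # --- outgroup (pirate) rules ---
    n_pirates: int = Field(default=3, ge=0)
    pirate_eat_mean_interval: float = Field(default=4.0, gt=0)
    pirate_eat_law: Literal["exponential", "fixed"] = "exponential"
    attack_cost: float = Field(default=10.0, gt=0)
    attack_window: float = Field(default=10.0, gt=0)
    message_display: float = Field(default=17.0, gt=0)

    # --- movement ---
    #: px/s; None means "calibrate so the inter-grove traversal takes 20 s".
    walk_speed: float | None = Field(default=None, gt=0)
    interaction_range: float = Field(default=60.0, gt=0)

    treatment: TreatmentParams

    @model_validator(mode="after")
    def _check(self) -> "WorldConfig":
        if abs(self.daylight_length + self.night_length - self.day_length) > 1e-9:
            raise ValueError(
                "clock inconsistency: daylight_length + night_length must equal "
                f"day_length ({self.daylight_length} + {self.night_length} != {self.day_length})"
            )
        if self.dusk_length >= self.daylight_length:
            raise ValueError("dusk_length must be shorter than daylight_length")
        if not (self.low_threshold < self.high_threshold < self.stock_cap):
            raise ValueError(
                "stock thresholds must satisfy low_threshold < high_threshold < stock_cap"
            )
        if self.n_fruiting_trees_per_grove > self.n_trees_per_grove:
            raise ValueError("n_fruiting_trees_per_grove exceeds n_trees_per_grove")
        if self.attack_cost > self.point_cap:
            raise ValueError("attack_cost cannot exceed point_cap")
        ticks = self.day_length / self.tick_length
        if abs(ticks - round(ticks)) > 1e-6:
            raise ValueError("tick_length must divide day_length")
        if self.view_width > self.world_width or self.view_height > self.world_height:
            raise ValueError("viewing window cannot exceed the world")
        if self.walk_speed is None:
            a, b = traversal_trees(self)
            dist = math.hypot(a.x - b.x, a.y - b.y)
            object.__setattr__(self, "walk_speed", dist / TRAVERSAL_CALIBRATION_S)
        return self


@dataclass(frozen=True)
class Tree:
    id: int
    grove: str  # "north" (smaller y) or "south"
    x: float
    y: float


def tree_layout(config: WorldConfig) -> list[Tree]:
    """Default tree coordinates: two horizontal bands of evenly spaced trees.

    The northern band is centered at 0.15 * world_height, the southern at
    0.85 * world_height (origin top-left, y grows southward).  Trees within a
    band are staggered by 50 px in y so "the southernmost tree in the north"
    and "the northernmost tree in the south" are unique; those two trees share
    an x coordinate, making the calibration traversal purely meridional.
    """
    n = config.n_trees_per_grove
    xs = [config.world_width * (i + 1) / (n + 1) for i in range(n)]
    north_y = config.world_height * 0.15
    south_y = config.world_height * 0.85
    trees = [Tree(i, "north", xs[i], north_y + 50.0 * i) for i in range(n)]
    trees += [Tree(n + i, "south", xs[i], south_y - 50.0 * i) for i in range(n)]
    return trees


def traversal_trees(config: WorldConfig) -> tuple[Tree, Tree]:
    """The southernmost northern tree and the northernmost southern tree."""
    trees = tree_layout(config)
    north = max((t for t in trees if t.grove == "north"), key=lambda t: t.y)
    south = min((t for t in trees if t.grove == "south"), key=lambda t: t.y)
    return north, south


@dataclass
class DailyFoodAssignment:
    """Which trees fruit today, how much, and where the grass is.

    ``flower_display`` shows tomorrow's allocation (flowers predict the next
    day's fruit exactly).  ``fruit_on_tree`` covers every tree, with zeros on
    non-fruiting trees, so that totals are straightforward sums.
    """

    day: int
    fruiting_trees: dict[str, tuple[int, ...]]
    fruit_on_tree: dict[int, int]
    flower_display: dict[int, int]
    grass_patch_locations: list[tuple[float, float]] = field(default_factory=list)


def _fruit_allocation(config: WorldConfig, day: int, food_seed: int) -> tuple[dict[str, tuple[int, ...]], dict[int, int]]:
    """Per-grove choice of fruiting trees and the 3:2:1-proportioned split.

    The first chosen tree receives the largest share (plus any rounding
    remainder), guaranteeing a unique largest fruit-bearing tree per grove.
    """
    rng = np.random.default_rng([food_seed, day, 0])
    n = config.n_trees_per_grove
    k = config.n_fruiting_trees_per_grove
    per_grove = config.treatment.fruit_per_day // 2
    weights = list(range(k, 0, -1))  # e.g. 3:2:1
    wsum = sum(weights)
    chosen: dict[str, tuple[int, ...]] = {}
    amounts: dict[int, int] = {t.id: 0 for t in tree_layout(config)}
    for grove, ids in (("north", range(n)), ("south", range(n, 2 * n))):
        picked = [int(i) for i in rng.choice(list(ids), size=k, replace=False)]
        base = [per_grove * w // wsum for w in weights]
        base[0] += per_grove - sum(base)  # remainder to the largest tree
        for tid, amt in zip(picked, base):
            amounts[tid] = amt
        chosen[grove] = tuple(picked)
    return chosen, amounts


def assign_daily_food(config: WorldConfig, day: int, food_seed: int) -> DailyFoodAssignment:
    """Build the day's food world: fruiting trees, amounts, flowers, grass.

    Deterministic in ``(config, day, food_seed)``; the flower display on day
    ``d`` equals the fruit allocation of day ``d + 1`` drawn from the same
    stream, so independent calls for consecutive days are consistent.
    """
    if not 0 <= day < config.n_days:
        raise ConfigError(f"day {day} outside the session range [0, {config.n_days})")
    chosen, amounts = _fruit_allocation(config, day, food_seed)
    _, flowers = _fruit_allocation(config, day + 1, food_seed)
    grass_rng = np.random.default_rng([food_seed, day, 1])
    grass = [
        (float(x), float(y))
        for x, y in zip(
            grass_rng.uniform(0.0, config.world_width, config.n_grass_patches),
            grass_rng.uniform(0.0, config.world_height, config.n_grass_patches),
        )
    ]
    return DailyFoodAssignment(
        day=day,
        fruiting_trees=chosen,
        fruit_on_tree=amounts,
        flower_display=flowers,
        grass_patch_locations=grass,
    )


def largest_fruiting_tree(assignment: DailyFoodAssignment, grove: str) -> int:
    """Tree id of the grove's largest fruit-bearing tree (unique by design)."""
    ids = assignment.fruiting_trees[grove]
    return max(ids, key=lambda tid: (assignment.fruit_on_tree[tid], -tid))


def make_treatment_config(name: str, **overrides) -> WorldConfig:
    """Construct a validated :class:`WorldConfig` for a named preset.

    ``overrides`` may set any WorldConfig field; treatment sub-fields can be
    overridden by passing a full ``treatment`` dict or TreatmentParams.
    """
    key = name.strip().lower()
    if key not in TREATMENT_PRESETS:
        raise ConfigError(
            f"unknown treatment preset {name!r}; valid presets: "
            + ", ".join(sorted(TREATMENT_PRESETS))
        )
    params = dict(overrides)
    params.setdefault("treatment", TreatmentParams(**TREATMENT_PRESETS[key]))
    try:
        return WorldConfig(**params)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def validate_config(config: WorldConfig) -> WorldConfig:
    """Re-run all invariant checks; returns the config unchanged if valid."""
    try:
        return WorldConfig.model_validate(config.model_dump())
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> WorldConfig:
    """Load a JSON config file: ``{"treatment": "bonobo", <field overrides>}``.

    Unknown keys are rejected.  ``treatment`` may be a preset name or a full
    parameter object.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a JSON object")
    treatment = data.pop("treatment", None)
    if treatment is None:
        raise ConfigError("config file must name a 'treatment'")
    if isinstance(treatment, str):
        return make_treatment_config(treatment, **data)
    try:
        return WorldConfig(treatment=TreatmentParams(**treatment), **data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def config_fingerprint(config: WorldConfig) -> str:
    """Stable short hash of the canonicalized configuration."""
    blob = json.dumps(config.model_dump(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
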