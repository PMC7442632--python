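"""Analysis statistics computed from session event logs.

Implements the full analysis layer: the nesting-proximity cohesion statistic
(mean of the unique pairwise distances among nested avatars, nC2 in the
denominator), time-of-day activity histograms, attack tallies by coalition
size and session half, vision-overlap group partitions, the exact small-sample
Mann-Whitney U test (full enumeration, no normal approximation), and OLS
trendlines for per-day series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import statsmodels.api as sm
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .sim_engine import Event, SessionLog
from .world_config import WorldConfig

__all__ = [
    "ProximitySeries",
    "ActivityHistogram",
    "AttackTally",
    "nest_positions_by_day",
    "nesting_proximity",
    "group_partition",
    "activity_histogram",
    "attack_tally",
    "mann_whitney_exact",
    "mann_whitney_critical_value",
    "ols_trend",
    "analyze_log",
]

DEFAULT_HALF_SPLIT_DAY = 17  # days 0..16 are the "first half" of 35


@dataclass
class ProximitySeries:
    """Per-day mean pairwise nesting distance (pixels).

    ``value`` is NaN on days with fewer than two nesters (flagged by
    ``missing``); such days are excluded from trend fits, never imputed.
    """

    day: np.ndarray
    n_nested: np.ndarray
    value: np.ndarray

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.value)


@dataclass
class ActivityHistogram:
    event_type: str
    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class AttackTally:
    """Attack outcomes classified by concurrent-attacker count {1, 2, >=3},
    split into session halves.  ``outcomes`` counts coalitions (one triple
    kill = one triplet); ``attacks`` counts individual attack events (one
    triple kill = three attacks)."""

    half_split_day: int
    outcomes: dict[str, dict[str, int]]
    attacks: dict[str, dict[str, int]]

    def total_attacks(self, half: str | None = None) -> int:
        if half is None:
            return self.total_attacks("first") + self.total_attacks("second")
        return sum(self.attacks[half].values())


def nest_positions_by_day(log: SessionLog) -> list[list[tuple[float, float]]]:
    """Nesting positions per day, extracted from nest_start events."""
    out: list[list[tuple[float, float]]] = [[] for _ in range(log.config.n_days)]
    for ev in log.events:
        if ev.type == "nest_start":
            out[ev.day].append((ev.x, ev.y))
    return out


def nesting_proximity(nest_positions: list[list[tuple[float, float]]]) -> ProximitySeries:
    """Mean unique pairwise distance among nested avatars, per day.

    With n nesters the denominator is C(n, 2) (66 for 12, 45 for 10); days
    with n < 2 are flagged missing.  The statistic is invariant to avatar
    relabeling and rigid translation, and scales linearly with coordinates.
    """
    days = np.arange(len(nest_positions))
    ns = np.array([len(p) for p in nest_positions])
    values = np.full(len(nest_positions), np.nan)
    for i, pts in enumerate(nest_positions):
        if len(pts) >= 2:
            d = pdist(np.asarray(pts, dtype=float))
            values[i] = d.sum() / len(d)  # len(d) == C(n, 2)
    return ProximitySeries(day=days, n_nested=ns, value=values)


def group_partition(positions: list[tuple[float, float]], config: WorldConfig) -> list[set[int]]:
    """Partition avatars into groups by overlapping ranges of vision.

    Two viewing windows (closed bounds) overlap iff their centers differ by at
    most view_width in x and view_height in y; groups are the connected
    components of that overlap graph (transitive closure).
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(positions)))
    for i, j in combinations(range(len(positions)), 2):
        xi, yi = positions[i]
        xj, yj = positions[j]
        if abs(xi - xj) <= config.view_width and abs(yi - yj) <= config.view_height:
            g.add_edge(i, j)
    return [set(c) for c in nx.connected_components(g)]


def activity_histogram(log: SessionLog, event_type: str, bin_width: float = 1.0) -> ActivityHistogram:
    """Counts of one event type per time-of-day bin, summed over all days."""
    if event_type not in ("groom", "forage_grass_unit", "forage_fruit", "call",
                          "attack", "nest_start"):
        raise ValueError(f"unknown or unbinnable event type {event_type!r}")
    daylight = log.config.daylight_length
    nbins = daylight / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin_width must divide daylight_length")
    edges = np.arange(0.0, daylight + bin_width / 2, bin_width)
    times = [ev.t for ev in log.events if ev.type == event_type]
    counts, _ = np.histogram(times, bins=edges)
    return ActivityHistogram(event_type=event_type, bin_width=bin_width,
                             bin_edges=edges, counts=counts)


def attack_tally(log: SessionLog, half_split_day: int = DEFAULT_HALF_SPLIT_DAY) -> AttackTally:
    """Classify every attack by the concurrency of its resolution.

    Each attack event must be covered by exactly one attack_outcome; an
    uncovered ("orphan") attack means the log is corrupt.  Outcomes voided by
    the end of a day are excluded from the tally but still cover their
    attacks.
    """
    classes = {1: "single", 2: "pair", 3: "triplet"}
    outcomes = {"first": {"single": 0, "pair": 0, "triplet": 0},
                "second": {"single": 0, "pair": 0, "triplet": 0}}
    attacks = {"first": {"single": 0, "pair": 0, "triplet": 0},
               "second": {"single": 0, "pair": 0, "triplet": 0}}
    pending: dict[tuple[int, int], Event] = {}
    for ev in log.events:
        if ev.type == "attack":
            pending[(ev.day, ev.actor, ev.payload.get("start"))] = ev
        elif ev.type == "attack_outcome":
            half = "first" if ev.day < half_split_day else "second"
            n = ev.payload["n_attackers"]
            covered = ev.payload.get("attackers", [])
            matched = 0
            for key in list(pending):
                if key[0] == ev.day and key[1] in covered:
                    del pending[key]
                    matched += 1
            if ev.payload["outcome"] == "void":
                continue
            cls = classes[min(n, 3)]
            outcomes[half][cls] += 1
            attacks[half][cls] += matched if matched else n
    if pending:
        day, actor, start = next(iter(pending))
        raise ValueError(
            f"corrupt log: attack by avatar {actor} on day {day} (t={start}) "
            "has no resolution outcome")
    return AttackTally(half_split_day=half_split_day, outcomes=outcomes, attacks=attacks)


def _u_from_ranks(rank_sum: float, n: int) -> float:
    return rank_sum - n * (n + 1) / 2.0


def mann_whitney_exact(sample_a, sample_b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    Returns ``(U, p)`` with U = min(U_a, U_b).  The p-value is the fraction of
    all C(n_a + n_b, n_a) equally likely group assignments of the pooled
    (mid-ranked) values whose min-U is at most the observed one.  Intended for
    the small samples the design produces (4 sessions per treatment).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    if na + nb > 20:
        raise ValueError("exact enumeration supported for n_a + n_b <= 20")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks under ties
    u_a = _u_from_ranks(ranks[:na].sum(), na)
    u_obs = min(u_a, na * nb - u_a)
    count = 0
    total = 0
    for idx in combinations(range(na + nb), na):
        total += 1
        ua = _u_from_ranks(sum(ranks[i] for i in idx), na)
        if min(ua, na * nb - ua) <= u_obs + 1e-9:
            count += 1
    return float(u_obs), count / total


def mann_whitney_critical_value(n_a: int, n_b: int, alpha: float = 0.05,
                                two_sided: bool = True) -> int:
    """Largest u with exact null P(U <= u) within the (per-tail) alpha budget.

    The null distribution of one group's U statistic is enumerated over all
    C(n_a + n_b, n_a) rank assignments; for a two-sided test the tail budget
    is alpha / 2.  Returns -1 if no rejection region exists (even U = 0 is too
    likely), e.g. for n_a = n_b = 1.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("sample sizes must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    bound = alpha / 2.0 if two_sided else alpha
    n = n_a + n_b
    us = []
    for idx in combinations(range(1, n + 1), n_a):
        us.append(_u_from_ranks(sum(idx), n_a))
    us = np.array(us)
    total = len(us)
    crit = -1
    for u in range(n_a * n_b + 1):
        if (us <= u + 1e-9).sum() / total <= bound:
            crit = u
        else:
            break
    return crit


def ols_trend(series, days=None) -> tuple[float, float]:
    """OLS slope (units/day) and two-sided p-value of a per-day series.

    NaN entries (e.g. days with fewer than two nesters) are dropped.  At
    least three non-missing points are required.
    """
    y = np.asarray(series, dtype=float)
    x = np.arange(len(y)) if days is None else np.asarray(days, dtype=float)
    mask = ~np.isnan(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 non-missing points for a trend fit")
    model = sm.OLS(y[mask], sm.add_constant(x[mask])).fit()
    return float(model.params[1]), float(model.pvalues[1])


def analyze_log(log: SessionLog, half_split_day: int = DEFAULT_HALF_SPLIT_DAY,
                histogram_bin_width: float = 1.0) -> dict:
    """Full per-session report: proximity series and trend, activity
    histograms, attack tallies, and end-of-session earnings."""
    prox = nesting_proximity(nest_positions_by_day(log))
    report: dict = {
        "fingerprint": log.fingerprint,
        "seed": log.seed,
        "treatment": log.config.treatment.name,
        "n_days": log.config.n_days,
        "proximity": {
            "day": prox.day.tolist(),
            "n_nested": prox.n_nested.tolist(),
            "value": [None if math.isnan(v) else v for v in prox.value],
        },
        "histograms": {},
        "final_points": {str(k): v for k, v in log.final_points.items()},
        "earnings_usd": {str(k): v for k, v in log.earnings_usd.items()},
    }
    try:
        slope, p = ols_trend(prox.value)
        report["proximity_trend"] = {"slope_px_per_day": slope, "p_value": p}
    except ValueError:
        report["proximity_trend"] = None
    for etype in ("groom", "forage_grass_unit", "forage_fruit"):
        h = activity_histogram(log, etype, histogram_bin_width)
        report["histograms"][etype] = {
            "bin_width": h.bin_width,
            "counts": h.counts.tolist(),
        }
    tally = attack_tally(log, half_split_day)
    report["attack_tally"] = {
        "half_split_day": tally.half_split_day,
        "outcomes": tally.outcomes,
        "attacks": tally.attacks,
        "total_attacks_first": tally.total_attacks("first"),
        "total_attacks_second": tally.total_attacks("second"),
    }
    return report
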