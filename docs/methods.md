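# Methods

## Model

`panworld` simulates a rectangular 6,720 × 10,500 px world in discrete 0.1-s
ticks over 35 days of 90 s (daylight 0–70 s, dusk 70–75 s, night 75–90 s).
Twelve avatars each carry a food stock and a grooming stock in [0, 10] and a
point balance in [0, 100]. Per tick and per resource, a stock strictly above
7 adds `point_gain_rate·dt` to points, strictly below 4 subtracts
`point_loss_rate·dt`, and the closed band [4, 7] is neutral; a nested avatar
additionally gains 0.3 points/s, and an avatar awake at night neither gains
nor loses. Digestion removes 4 food units at mid-daylight (t = 37.5 s) and 7
at the last tick of the day (t = 89.9 s), floored at zero. Grooming is
directional (+1 unit to the recipient, 4-s cooldown per groomer, no
self-grooming) and the grooming stock depletes only with distance walked.

Food comes as fruit (one unit per piece, one piece per `fruit_handle_time`,
irreversibly consumed) on 3 of 5 trees per grove, and as grass (one unit per
`grass_time_multiplier × fruit_handle_time` seconds of uninterrupted grazing,
patches never deplete within a day, shared without interference). The two
treatments differ only in `fruit_per_day` (120 vs 40) and the grass
multiplier (10 vs 3.33). Because usable intake is capped by the stock
ceiling and the 4 + 7 digestion schedule, the *attainable* daily intake of a
lone forager is 11 units/day in both treatments — the equal-aggregate-food
design goal — which the `estimate_max_daily_intake` diagnostic verifies by
simulation.

One pirate per day spawns at the largest fruiting tree of a uniformly chosen
grove, at a time uniform over [0, 70) s, and eats one fruit per
exponentially distributed interval with a 4-s mean (a deterministic 4-s law
is selectable). Attacks require ≥ 10 points and proximity; each creates a
10-s beam. The instant three or more beams are live, the pirate dies (and
that pirate index never returns; after three deaths no pirate ever spawns).
When the first beam of a two-beam overlap expires, the pirate flees for the
day at no cost to either attacker. A beam that expires having never
overlapped another costs its attacker exactly 10 points. The two in-world
notices ("Pirates will be scared away if 2 avatars attack it simultaneously,
…", "3 simultaneous attackers will kill this pirate, …") display for 17 s to
avatars whose viewing window contains the pirate.

### Information model

Policies receive only an `Observation`: own state, entities inside the
1584 × 947 px window (closed bounds), the map overlay of tree *locations*
(never fruiting state), bearings (unit vectors, no identity) of calls heard
within 2,200 px, and displayed notices. This reproduces the information
asymmetry of the original interface; no scripted policy can act on hidden
state. The one deliberate exception, `OmniscientForager`, recomputes the
food schedule from the seed and exists solely for the intake-parity
diagnostic.

## Parameters the source never printed

These are design choices, exposed in `WorldConfig` with the defaults below:

| parameter | default | rationale |
| --- | --- | --- |
| `tick_length` | 0.1 s | resolves the 4-s cooldowns and 10-s beams exactly; 31,500 ticks/session |
| `walk_speed` | derived ≈ 347.5 px/s | calibrated so the traversal between the southernmost northern tree and the northernmost southern tree takes 20 s (22% of the day) |
| `fruit_handle_time` | 1.0 s | single free time constant; grass then takes 10 s / 3.33 s per unit |
| `point_gain_rate`, `point_loss_rate` | 0.1 points/s per resource | unconstrained by the source ("increased each second"); documented free parameter |
| `groom_walk_depletion` | 0.002 units/px | ≈ 1 unit per 500 px walked |
| `interaction_range` | 60 px | foraging / grooming / attacking contact distance |
| `initial_stock` | 5 units | inside the neutral band, so day-1 points are not bled before any behavior occurs |
| digestion instants | t = 37.5 s and t = 89.9 s | literal "middle of the day" and "before dawn" |
| within-grove fruit split | 3:2:1 (remainder to the largest) | deterministic, guarantees a unique largest fruit-bearing tree for the pirate spawn rule |
| tree layout | bands at 0.15 / 0.85 of world height, 50-px stagger | makes "southernmost northern" / "northernmost southern" trees unique and vertically aligned |
| session halves | days 1–17 vs 18–35 | parameter of `attack_tally`; the half-split day is not otherwise defined |

Numerical conventions: grass-unit times are quantized *up* to the tick (the
3.33× unit takes an effective 3.4 s, the 10× unit exactly 10.0 s); the stock
thresholds 4 and 7 are inclusive on both ends of the neutral band;
simultaneous contested actions (e.g. the last fruit) execute in ascending
avatar id; a beam is live through its expiry tick, so a third attacker
landing on the very tick a pair would resolve still produces a kill (kill
precedes flee within a tick). A live pirate remains until the day ends (the
source states only that a *dead* pirate disappears at night), so beams begun
in late daylight still resolve; beams open at the day rollover are voided
with an explicit outcome record.

Randomness: one master seed is split (via `SeedSequence`) into independent
named streams — daily food placement, pirate spawning, pirate eating, and one
stream per policy — so environment randomness is invariant to policy changes
and every log is byte-reproducible.

## The synthetic sessions

`generate_fixture_session` replaces the human groups with scripted foragers.
They are demonstrative, not cognitive models:

* `split_grove_frugivores` (*Chimpanzee*-like): six avatars per grove forage
  fruit greedily, drift to the grove center and groom when sated, and
  converge on a visible pirate, firing only when at least two allies are
  already in contact range — so attacks land as coalitions whenever three
  arrive, with occasional solo penalties and pair-flees when they do not.
* `herd_grazers` (*Bonobo*-like): all twelve graze until sated, groom and
  stay leashed to visible companions, announce grass patches with calls
  (between grass units, when grazing progress is at zero), answer calls that
  do not point at anyone already visible, and march on a shared per-day
  migration heading while searching. Avatars start mutually out of sight and
  earshot, so the herd assembles gradually over days through chance
  encounters and call chains.

What a green directional test establishes: under identical mechanics, the
dispersed-food preset with affiliative grazers produces a *declining*
nesting-proximity trend (one large nesting aggregation by the final third)
and zero attacks, while the clumped-food preset with grove-bound frugivores
produces two persistent nesting clusters and repeated coalitionary attacks,
including pirate kills. What it does not establish: anything about human
play. The scripted policies do not reproduce the human sessions' earnings
levels or their between-treatment earnings parity (realized points depend
strongly on how much a policy walks), their daily activity rhythms, or the
archived numerical results; those require the archived human data, which the
analysis layer can ingest via the tabular log dialect but which no test
fetches.

## Statistics

* **Nesting proximity** — per day, the sum of unique pairwise Euclidean
  distances among nested avatars divided by C(n, 2); days with fewer than
  two nesters are flagged missing and excluded from trend fits (never
  imputed). Invariant to relabeling and translation; scales linearly.
* **Group partition** — avatars whose viewing windows overlap (|Δx| ≤ 1584
  and |Δy| ≤ 947, closed) are linked; groups are connected components
  (transitive closure), computed with networkx and cross-checked against a
  union-find oracle in tests.
* **Exact Mann–Whitney** — `mann_whitney_exact` enumerates all
  C(n₁+n₂, n₁) assignments of the pooled mid-ranked values and reports
  U = min(U₁, U₂) with the exact two-sided p (fraction of assignments at
  least as extreme). `mann_whitney_critical_value` enumerates the null U
  distribution and returns the largest u with P(U ≤ u) ≤ α/2 (−1 when no
  rejection region exists, e.g. n = 1, 1). For n = 4, 4 and α = 0.05 the
  critical value is 0 and a fully separated pair of samples has
  p = 2/70 ≈ 0.0286; the exact p and the critical-value comparison are
  reported separately rather than conflated.
* **Attack tally** — every attack is classified by the concurrency of its
  resolution (single / pair / triplet); one triple kill is one coalition but
  three attack events, and both countings are reported, split at the
  configurable half-split day. Orphan attacks (no covering outcome) are a
  log-corruption error.
* **Trends** — OLS of the per-day series on the day index (statsmodels),
  slope in px/day with the two-sided t-test p-value.

## Known limitations

* The scripted policies' constants (leash radius, call periods, satiation
  target 8, attack-coordination rule) were chosen for behavioral
  plausibility, and the directional contrast is robust across seeds, but no
  claim is made that they are unique or optimal.
* Dusk is a phase label only (no visibility change), and calling carries no
  cost or cooldown; both match the mechanics as specified but are untested
  against the original implementation.
* With 40 fruit split 3:2:1 per grove, a bonobo-treatment tree can bear as
  few as 3 fruit; the split rule is a convention, not an observed value.
* The pirate idles (rather than relocating) when its tree empties, and a
  fled or surviving pirate's within-day position never changes.
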