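# panworld

A deterministic, headless virtual-world model of ape socioecology, plus the
statistics to analyze what happens in it.

Socioecological theory links the distribution and value of food to primate
social structure: a clumped, high-value, ephemeral resource (ripe fruit)
should favor small competitive subgroups and aggression toward outgroup
competitors, while an evenly spread, low-value, inexhaustible resource
(terrestrial herbaceous vegetation, "grass") should favor large tolerant
groups — the classic contrast between chimpanzees and bonobos. `panworld`
implements a 12-avatar foraging world in which exactly this contrast can be
switched on and off by a single treatment parameter bundle, with pluggable
agent policies in place of players, so the hypothesis can be exercised
computationally at desk scale.

## The world in one paragraph

A session is 35 "days" of 90 s each (75 s daylight, the last 5 of them dusk,
then 15 s of night) on a 6,720 × 10,500 px map with five fruit trees in a
northern grove and five in the south. Each day, 3 of 5 trees per grove bear
fruit (flowers reveal tomorrow's allocation) and 8 grass patches appear at
random. The *Chimpanzee* treatment supplies 120 fruit/day and makes a grass
unit take 10× a fruit's handling time; *Bonobo* supplies 40 fruit/day with
grass at 3.33× — equal aggregate food, different optimal foraging. Avatars
hold a food stock and a grooming stock, both capped at 10; stocks above 7
grow the avatar's points (convertible 1:1 to dollars), stocks below 4 drain
them, and digestion removes 4 units mid-day and 7 before dawn (12 × 11 = 132
> 120, so fruit is always scarce). Avatars see only a 1584 × 947 px window,
hear calls within 2,200 px (bearing only), nest at night for 0.3 points/s,
and may attack a fruit-stealing "pirate" at a 10-point stake: a lone
10-second attack beam costs its attacker 10 points, two simultaneous beams
scare the pirate off for the day, three kill it — and there are only three
pirates per world.

## Worked example

Run the two canonical synthetic sessions (scripted policies stand in for
human players; see `docs/methods.md` for what they do and do not emulate):

```bash
panworld fixtures --seed 1 --out-dir fixtures/
panworld analyze --log fixtures/bonobo_herd_grazers_seed1.jsonl --out bonobo.json
panworld analyze --log fixtures/chimpanzee_split_grove_frugivores_seed1.jsonl --out chimp.json
panworld report  --log fixtures/bonobo_herd_grazers_seed1.jsonl --out-dir figures/
```

With seed 1 the reports contain, among much else:

| quantity | *Chimpanzee* + split-grove frugivores | *Bonobo* + herd grazers |
| --- | --- | --- |
| nesting proximity, day 1 → day 35 | 3 894.8 → 3 994.9 px | 4 129.7 → 0.0 px |
| proximity trend (OLS) | −5.6 px/day (p = 0.019) | −82.1 px/day (p = 0.0001) |
| attacks, first / second half | 18 / 1 | 0 / 0 |
| attack outcomes (single/pair/triplet) | 3 / 5 / 2 | 0 / 0 / 0 |

Nesting proximity is the cohesion statistic: the sum of the unique pairwise
distances among the avatars that nested that night, divided by C(n, 2) — 66
combinations when all 12 nest, 45 when only 10 do. The frugivore sessions
split into two grove-bound subgroups (proximity stays near the inter-grove
distance) and keep attacking the pirate, killing pirates by threes; the
grazer sessions assemble into a single herd (proximity collapses toward
zero) and never attack. That is the qualitative treatment contrast the world
was designed to induce.

The analysis layer also provides the exact small-sample Mann–Whitney U test
used to compare four sessions per treatment: `mann_whitney_exact` enumerates
all C(8, 4) = 70 rank assignments (for n = 4, 4 the two-sided critical value
at α = 0.05 is 0), rather than using a normal approximation.

## Library surface

- `panworld.world_config` — validated session parameters
  (`make_treatment_config`, `load_config`), the daily food assignment.
- `panworld.sim_engine` — `run_session(config, policies, seed) → SessionLog`;
  0.1-s ticks, byte-identical logs for identical inputs.
- `panworld.outgroup` — pirate lifecycle and the 1/2/3-attacker resolution.
- `panworld.agent_policies` — the policy contract (`Observation → Action`)
  and scripted baselines (`split_grove_frugivores`, `herd_grazers`, `mixed`).
- `panworld.metrics_stats` — nesting proximity, vision-overlap group
  partition, activity histograms, attack tallies, exact Mann–Whitney,
  OLS trends; `analyze_log` for a full JSON report.
- `panworld.logio` / CLI `panworld` — JSON Lines event logs (schema-versioned,
  round-tripping), a flat CSV dialect for external data, and the
  `simulate` / `analyze` / `fixtures` / `report` subcommands.

## Acceptance script

`scripts/acceptance.py` recomputes the package's analytic reference
quantities from scratch — the exact Mann–Whitney critical value for n = 4, 4;
the lone-attacker penalty measured in a simulated session; the inter-grove
traversal time at the calibrated walking speed; and the pirate's long-run
mean eating interval — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
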