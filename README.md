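# arnet

Egocentric influence-network analysis for allergic rhinitis (AR) management
surveys. The package implements a complete, tested pipeline around the
concentric-circle "influence map" design: each participant (*ego*) nominates
influences (*alters* — GP, pharmacist, own experience, internet, ...) and
places each on one of four concentric circles (Circle One = most
influential, Circle Four = little influence).

## What it does

- **instruments** — classifies the single AR-severity question into five
  categories and scores the mini-RQLQ quality-of-life questionnaire
  (mean of items on a 0–6 scale), binning the mean into four impairment
  categories (ZERO = {0}, MILD = (0,2], MOD = (2,4], SEV = (4,6]).
- **naming** — canonicalises free-text alter labels into a versioned
  14-category taxonomy (shipped as `src/arnet/data/taxonomy.yaml`,
  swappable), and detects name-generation *saturation*: the last interview
  index at which a first-appearance alter category was introduced.
- **model** — the ego/placement data model, cohort aggregation into
  per-alter circle counts n1..n4, and QOL-stratified sub-cohorts.
  Duplicate nominations of one category by one ego collapse to the
  innermost circle.
- **density** — the weighted influence statistic:
  `alter_score = 4·n1 + 3·n2 + 2·n3 + 1·n4` and
  `network alter density = 100 · alter_score / Σ alter_scores`,
  plus Circle-One composition, network-size summaries, and a shared
  half-away-from-zero percentage rule used for every printed number.
- **io** — long-format CSV cohort tables, a NetDraw-compatible VNA dialect
  (`*node data` / `*tie data` sections, tie strength = circle weight,
  lossless round-trip), and structured JSON/text reports.
- **synth** — a calibrated synthetic-cohort generator (the study's raw data
  are not public): QOL-conditioned network sizes, weighted alter
  nomination with an HCP gradient, per-category circle distributions, and
  mini-RQLQ items drawn so the mean lands in the drawn QOL bin; fully
  reproducible from a seed, with a parameter-recovery harness.

## CLI

```sh
# generate a synthetic 41-ego cohort table
arnet simulate --n 41 --seed 7 --out cohort.csv

# analyse it: report.json, report.txt, aggregate + per-QOL (+ per-ego) VNA files
arnet analyze cohort.csv --outdir out/ --seed 7 --per-ego

# render a stored report as text tables
arnet report out/report.json
```

`analyze` accepts `--taxonomy my_taxonomy.yaml` and `--qol-bins "2,4,6"`
to override the alter taxonomy and QOL bin edges.

## Cohort table format

CSV, long format — one row per placement, participant fields repeated:

```
participant_id,age,sex,region,severity_response,rqlq_items,rqlq_mean,alter_label,circle
p0001,34,F,metropolitan,Never,1.2;0.8;...,,gp,1
```

Provide either `rqlq_items` (semicolon-separated, each 0–6) or a
precomputed `rqlq_mean`. `severity_response` must be one of the five
canonical response strings; `alter_label` must resolve in the taxonomy.

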