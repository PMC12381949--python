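# excessrisk

Second-cancer excess-risk analysis for a breast-cancer cohort followed against
external reference rates, with a synthetic cohort generator standing in for
registry data.

The pipeline covers:

- **`excessrisk.rates`** — reference ("national") incidence-rate tables on an
  attained-age band × calendar year × deprivation-fifth grid, plus a
  deterministic synthetic generator (log-linear in age, optional calendar
  drift and deprivation gradient).
- **`excessrisk.simulate`** — cohort simulation from piecewise-constant
  cause-specific hazards (reference rate × configured multipliers), with exact
  inverse-transform sampling within each constant-hazard segment. Configured
  multipliers are the true SIRs/rate ratios, so every downstream stage is
  testable by parameter recovery.
- **`excessrisk.persontime`** — eligibility rules (applied sequentially with
  per-rule exclusion counts), at-risk intervals (entry at diagnosis + 3
  months; exit at first qualifying event, 85th birthday, death, or the
  administrative date), Lexis splitting, and observed/expected/woman-years
  tallies per stratum. Reference breast rates are halved for contralateral
  analyses.
- **`excessrisk.sir`** — standardised incidence ratios (O/E) and absolute
  excess rates ((O−E)/woman-years per 10 000) with exact (Garwood) Poisson
  intervals, treating expected counts as fixed.
- **`excessrisk.cumrisk`** — the two-step cumulative-risk estimator under
  competing risks on annual windows, its "expected" counterpart built from
  reference rates combined with the cohort's observed competing hazards, and
  woman-level bootstrap bands for the excess.
- **`excessrisk.regression`** — Poisson rate-ratio regression for adjuvant
  treatments with stratum absorption by profiling (equivalent to one dummy
  per stratum, verified), likelihood-ratio P values, Wald intervals,
  follow-up-period splits at 10 years, and the directional P < 0.01 decision
  rule.
- **`excessrisk.attribution`** — attributable fractions ((RR−1)/RR), excess
  counts among the exposed, and scenario sums (trial-consistent vs all
  flagged associations).
- **`excessrisk.io` / `excessrisk.cli` / `excessrisk.pipeline`** — CSV/JSON
  I/O with exact round-tripping, a cancer-type grouping map, validated run
  configuration, and an orchestrated end-to-end run with config-stamped
  outputs.

## CLI

```sh
excessrisk simulate --n 5000 --seed 1 --out-dir out          # cohort + rates
excessrisk tabulate --cohort out/women.csv --events out/events.csv \
    --rates out/rates.csv --target lung --out-dir out        # tallies
excessrisk all --config run.json                             # full pipeline
```

A minimal `run.json`:

```json
{"simulate_n": 5000, "seed": 1, "out_dir": "out",
 "targets": [{"target": "lung"},
             {"target": "breast", "contralateral": true}]}
```

Outputs (`eligibility.csv`, `tally_*.csv`, `sir_aer.csv`, `cif_*.csv`,
`rate_ratios.csv`, `attribution.csv`, `summary.csv`) are CSVs with a
`#`-prefixed metadata header carrying the config hash and seed. Exit codes:
2 configuration error, 3 data error, 4 numerical error.

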