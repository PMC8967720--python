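# ceakit

A tested pipeline for trial-based and model-based cost-utility analysis of
a group exercise programme for older adults at risk of mobility decline:

- **`ceakit.costing`** — micro-costing of programme delivery from a
  YAML resource specification (per-session / per-participant / per-group /
  shared bases), with equivalent-annual-cost annuitization for capital
  items. Exact Decimal arithmetic; rounding only at report rendering.
- **`ceakit.valuation`** — health-profile → utility lookup against
  value-set tables, and discounted QALYs over 24 months by the
  area-under-the-curve method (second year discounted at 3.5%).
- **`ceakit.resources`** — NHS/PSS resource-use costing per 6-month
  recall period, neighbour-mean imputation of the unmeasured 12–18-month
  period, and discounted 24-month totals.
- **`ceakit.imputation`** — multiple imputation by chained equations with
  predictive mean matching (type-1, Bayesian coefficient draws, k-donor
  pools), and Rubin's-rules pooling with Barnard–Rubin degrees of freedom.
- **`ceakit.cea`** — covariate-adjusted incremental costs and QALYs
  (gaussian-identity or gamma-log GLMs), ICER / dominance classification
  with reporting granularity, within-arm case-resampling bootstrap,
  CEACs, and net monetary benefit.
- **`ceakit.markov`** — lifetime extrapolation over 14 states (SPPB 0–12
  plus dead), annual cycles, proportional-odds transition model fitted to
  control-arm panels, life-table mortality identical in all living states,
  state cost/utility regressions, and population-weighted aggregation.
- **`ceakit.sensitivity`** — probabilistic sensitivity analysis over
  parameter distributions (beta/gamma/normal/lognormal/dirichlet/fixed)
  with percentile credible intervals and CEACs, plus one-way deterministic
  analysis with tornado ordering.
- **`ceakit.synthetic`** — trial-like data with known ground truth
  (configurable incremental QALYs/costs, SPPB effect, MAR missingness
  with an exact complete-case fraction), toy value sets hitting the
  published instrument floors, and a toy Gompertz life table.
- **`ceakit.pipeline`** — end-to-end within-trial analysis:
  profiles → utilities → period costs → imputation → adjusted
  increments → pooled estimates.

## Command line

Everything is exposed under one entry point:

```sh
ceakit simulate --n 777 --seed 1 --out data/        # synthetic trial + value sets + life table
ceakit cost --sessions 64 --group-size 15.2 --out costing.csv
ceakit costs --counts data/participants.csv --prices data/unitcosts.csv --out costs.csv
ceakit impute --in derived.csv --m 50 --seed 7 --out imputed/
ceakit cea --data data/participants.csv --value-set data/valueset_crosswalk.csv \
           --prices data/unitcosts.csv --m 50 --bootstrap 10000 --seed 11 --out results/
ceakit markov --config model.yaml --life-table data/lifetable.csv \
              --data data/participants.csv --out model_results/
ceakit psa --config model.yaml --life-table data/lifetable.csv \
           --dists dists.yaml --n 5000 --seed 3 --out psa/
ceakit oneway --config model.yaml --life-table data/lifetable.csv \
              --ranges ranges.yaml --out tornado.csv
```

`ceakit cost` defaults to the packaged costing specification in
`src/ceakit/data/programme_costing.yaml`.

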