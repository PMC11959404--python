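# mvgt

Multivariate generalizability theory for paired operative-rating data.

Workplace-based surgical assessments pair a faculty and a trainee rating of
the same procedure on four score variables: faculty/trainee autonomy
(4-level scale) and faculty/trainee performance (5-level scale). `mvgt`
treats these as a trainees × procedures crossed design with the four
variables as a fixed multivariate facet and provides:

- **`mvgt.simulate`** — a synthetic rating-data generator with known
  ground-truth variance/covariance components (continuous latent or
  ordinal via threshold discretization), so every downstream stage is
  testable against truth;
- **`mvgt.sampling`** — stratification by PGY × case complexity, the
  minimum-trainees-per-procedure filter, and thinning to a balanced
  *k*-procedures-per-trainee design;
- **`mvgt.gstudy`** — multivariate G-study estimation: exact
  expected-mean-square solution on balanced crossed tables, REML with a
  sum/difference covariance construction on unbalanced ones (the two agree
  to 1e-6 relative tolerance in balance);
- **`mvgt.dstudy`** — composite D studies: universe-score variance,
  relative/absolute error variance, generalizability coefficient (Eρ²),
  index of dependability (Φ), SEM, reliability curves, and the minimum
  number of procedures reaching a reliability threshold;
- **`mvgt.interrater`** — role means and the dis-attenuated (universe
  score) faculty–trainee correlation per item;
- **`mvgt.pipeline` / CLI** — a deterministic end-to-end run that writes
  component JSON, report CSVs, reliability curves, and a manifest.

## CLI

```sh
# generate synthetic data from a YAML/JSON config
mvgt simulate sim.yaml data.csv --seed 7

# thin to 3 procedures/trainee, dropping procedures with <50 trainees
mvgt sample data.csv sampled.csv --procedures-per-trainee 3 --min-trainees 50 \
    --stratum PGY5:average --seed 7

# G study (balanced EMS or REML, auto-detected) and D study
mvgt gstudy sampled.csv components.json --report gstudy.csv
mvgt dstudy components.json --threshold 0.8 --criterion dependability --n-max 50

# inter-rater statistics
mvgt interrater sampled.csv components.json --out-csv interrater.csv

# everything at once, per stratum, into a report bundle
mvgt run-all --sim-config sim.yaml --out-dir out --seed 7
```

Exit codes: `0` success, `2` validation error, `3` infeasible design after
filtering.

A simulation config file looks like:

```yaml
n_trainees: 300
n_procedures: 20
procedures_per_trainee: 0   # 0 = fully crossed
sigma_t: [[0.06, 0, 0, 0], [0, 0.09, 0, 0], [0, 0, 0.03, 0], [0, 0, 0, 0.10]]
sigma_p: [[0.04, 0, 0, 0], [0, 0.08, 0, 0], [0, 0, 0.01, 0], [0, 0, 0, 0.02]]
sigma_tp: [[0.32, 0, 0, 0], [0, 0.31, 0, 0], [0, 0, 0.22, 0], [0, 0, 0, 0.15]]
grand_means: [2.4, 2.3, 3.0, 2.7]
cutpoints: {}               # empty = continuous latent scores
pgy_label: 5
complexity_label: average
missing_rate: 0.0
seed: 7
```

## Notes

- Ordinal ratings are analyzed as numeric values, matching how the source
  analysis reports means/SDs; the generator's continuous mode is the exact
  test surface for parameter recovery.
- Negative variance estimates are truncated to zero for reporting and D
  studies (raw values are kept on the result object and logged);
  covariances are then clipped to the Cauchy–Schwarz bound.
- The reported `ci95_margin` follows the source convention of one SEM; a
  conventional 1.96·SEM half-width is also emitted
  (`ci95_margin_conventional`).
- In one published component table the parenthesized percentage columns for
  the two middle variables are mutually swapped relative to their own
  components; `proportion_table` always reports percentages computed from
  the components themselves.
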