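# File formats

All files are plain UTF-8 CSV with a header row, "." as the decimal
separator, and ages as floating-point days (0 = start of adult life).

## Life table (`read_life_table` / `write_life_table`)

One row per (age, vial) observation.

| column    | required | meaning                                          |
|-----------|----------|--------------------------------------------------|
| `age`     | yes      | chronological age, days                          |
| `vial`    | yes      | replicate label (any string; `all` for pooled)   |
| `n_alive` | yes      | number of living individuals in the vial, >= 0   |
| `n_smurf` | no       | number of *living* phase-2 individuals, <= n_alive; omit the column (or leave cells empty) when the assay did not score phase-2 status |

Counts may be fractional (e.g. fractions of an initial population when
exporting a deterministic trajectory). Within a vial, `n_alive` should
be non-increasing with age; violations raise a warning on read (an
error with `strict_monotone=True`). The initial population size per
vial is inferred as the vial's maximum `n_alive` unless supplied
explicitly in code.

Example:

```csv
age,vial,n_alive,n_smurf
0,v1,30,0
10,v1,28,2
20,v1,21,5
```

## Event table (`read_events` / `write_events`)

One row per individual in a longitudinal assay.

| column           | required | meaning                                     |
|------------------|----------|---------------------------------------------|
| `id`             | yes      | individual identifier                       |
| `vial`           | yes      | replicate label                             |
| `transition_age` | yes      | age at the phase-1/phase-2 transition, days |
| `death_age`      | yes      | age at death, days; must exceed `transition_age` |
| `censor_age`     | no       | age at loss to follow-up; event columns after this age are empty |

Event ages are continuous; daily-resolution scored ages
(`obs_transition_age`, `obs_death_age` = the first whole day at or
after the event) are reconstructed on read when absent.

Example:

```csv
id,vial,transition_age,death_age,censor_age
0,v1,21.37,24.11,
1,v1,14.02,15.68,
2,v2,30.51,,28.0
```

## JSON results

Fit and statistics subcommands emit JSON objects with stable keys and a
`provenance` block (package version, format version, seed where
randomness is involved, SHA-256 of the input file) so that runs can be
reproduced and compared byte-for-byte (timestamps are deliberately not
recorded).
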