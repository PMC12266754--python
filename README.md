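# irpipe

Immune-resilience (IR) transcriptomic analysis pipeline:

- **signatures** — z-score expression per gene, score oriented gene
  signatures (GMT with `NAME_UP`/`NAME_DN` orientation pairing), split at
  the cohort median (H strictly above, L at or below), and combine a
  survival-associated and a mortality-associated signature into the four
  IR profiles `H-L`, `H-H`, `L-L`, `L-H`; single-gene TCF7 strata and
  signature correlation/clustering utilities.
- **ihg** — immune health grades I–IVc from absolute CD4/CD8 T-cell
  counts (configurable ratio/CD4 cut-offs), extreme-degrader flag
  (IIc/IVc), grade prevalences, and a logistic prevalence-vs-age fit.
- **triad** — pathogenic-triad burden: weighted mean of the three
  {−}-salutogenesis readouts minus the three {+} readouts (plus a 0–6
  adverse-strata count mode) and linear-model group contrasts with LRT
  p-values.
- **trajectories** — classify per-subject ordered profile sequences into
  preserver / reconstituter / degrader (non-optimal baselines are
  explicitly `not-classifiable`), group mean±SE trajectory summaries,
  and state-transition tables.
- **survival** — Cox PH fitting (lifelines, Efron ties), hazard ratios,
  the hazard-equivalence-age statistic (closed form `gap =
  beta_group/beta_age` with a delta-method CI, plus a root-finding
  variant for non-linear age terms), age-stratified HRs, and
  Kaplan–Meier/log-rank utilities.
- **screens** — feature-wise FDR-controlled regression screens
  (linear/logistic), a hand-rolled Benjamini–Hochberg step-up,
  discovery-set overlap, octile dose–response with a logistic fit, and
  2×2 contingency summaries (odds ratio, Fisher exact, chi-square).
- **synthetic** — deterministic generators for all of the above:
  factor-model signature blocks with closed-form within-set correlation,
  exponential PH survival with planted group effects, trajectory
  mixtures, grade-targeted CD4/CD8 counts, and proteomic tables with
  planted associations. Every stage has a planted-parameter recovery
  test.
- **recovery** — simulation loops that recover the headline survival
  quantities (HR ≈ 9.71, equivalence age ≈ 55.5 y, survival gap ≈ 15.5 y,
  midlife HR ≈ 0.31, stratum HR ≈ 3.0).

## CLI

```sh
irpipe --seed 1 --out-dir sim simulate --n-subjects 500
irpipe --out-dir out score --expression sim/expression.tsv --gene-sets sets.gmt
irpipe --out-dir out ihg --phenotypes sim/phenotypes.csv
irpipe --out-dir out triad --scores out/scores.tsv \
    --pos IMM-AGE,EL_down,tTCH_high --neg Age_IL6_up,InflammDage_up,SenMayo
irpipe --out-dir out trajectory --long longitudinal.csv
irpipe --out-dir out survive --phenotypes pheno.csv --ref-age 40
irpipe --out-dir out screen --features proteins.csv --phenotypes pheno.csv \
    --response-col sas_score --covariate-cols age,sex
irpipe --out-dir out run --expression sim/expression.tsv --gene-sets sets.gmt \
    --phenotypes sim/phenotypes.csv
```

Phenotype CSVs are long format with fixed column names (`subject`,
`timepoint`, `age`, `sex`, `cd4`, `cd8`, `time`, `event`); each stage
only requires the columns it uses. Expression is TSV (gene id column +
sample header) or an MTX triplet with row/column annotation files.

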