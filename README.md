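# mrpipe

A two-sample Mendelian randomization (MR) pipeline for GWAS summary
statistics, built around a synthetic-data module with known causal truth so
every stage can be validated end to end:

- **`mrpipe.sumstats`** — read/validate/write tab-separated summary-statistics
  tables (canonical columns `snp, chr, pos, ea, oa, eaf, beta, se, pval, n,
  n_case, n_control`; arbitrary source headers via a dialect mapping).
- **`mrpipe.simulate`** — exposure/mediator/outcome triples generated from a
  structural causal model (instrument effects, mediated and direct paths,
  balanced/directional pleiotropy, LD blocks, palindromic SNPs, allele-coding
  flips), plus the implied pairwise r² matrix.
- **`mrpipe.instruments`** — instrument selection: p-value filter, greedy LD
  clumping (r² < 0.001 within a 10,000 kb window by default), F-statistic
  filter (F ≥ 10), outcome-association screen (p < 1e-5), and an explicit
  exclusion list; per-stage removal audit.
- **`mrpipe.harmonize`** — effect-allele alignment between datasets, with
  frequency-based orientation of palindromic SNPs (ambiguity zone
  [0.42, 0.58] dropped) and a per-SNP action audit.
- **`mrpipe.estimators`** — Wald ratio, IVW (fixed and multiplicative
  random effects), MR-Egger (slope + intercept pleiotropy test), weighted
  median, weighted mode; odds-scale conversion of any estimate.
- **`mrpipe.sensitivity`** — Cochran's Q, leave-one-out re-estimation,
  Steiger directionality test, funnel-plot data.
- **`mrpipe.screening`** — batch MR across exposure/outcome panels with
  Benjamini–Hochberg FDR adjustment per outcome family and tier assignment
  (`highly_correlative` adj-p < 0.05; `suggestive` raw p < 0.05 and
  adj-p < 0.2); reverse screening with swapped roles.
- **`mrpipe.mediation`** — multivariable MR (zero-intercept weighted least
  squares of outcome on exposure + mediator effects) and the two-step
  mediation decomposition: mediation = βa·βb (delta-method CI), direct =
  total − mediation, proportion = mediation/total × 100%.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: published-table
arithmetic identities, estimator-vs-oracle equivalences, null calibration
(Q p-value uniformity, FDR tier rate), 100-replicate parameter recovery of
the mediation decomposition, and harmonization/clumping invariances.

## CLI

```sh
mrpipe simulate --config sim.yaml --out-dir sim/
mrpipe select   --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
                --r2 sim/ld_r2.tsv --out-dir sel/
mrpipe harmonize --exposure sel/instruments.tsv --outcome sim/outcome.tsv \
                 --out-dir harm/
mrpipe estimate --harmonized harm/harmonized.tsv --out-dir est/
mrpipe screen   --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
                --r2 sim/ld_r2.tsv --out-dir screen/
mrpipe mediate  --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
                --outcome sim/outcome.tsv --r2 sim/ld_r2.tsv --out-dir med/
```

All stages exchange tab-separated text; stage counts are logged to stderr.

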