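# mrpipe

Two-sample Mendelian randomization (MR) on GWAS summary statistics, as a
tested, reusable Python package:

- **`mrpipe.summary_data`** — data model, validation and TSV I/O for
  per-SNP association tables, long-format LD (r²) tables and result tables.
- **`mrpipe.instrumenting`** — instrument selection at genome-wide
  significance (P < 5×10⁻⁸), allele harmonization between exposure and
  outcome tables (including frequency-based strand inference for palindromic
  SNPs), greedy LD clumping (r² < 0.001), and instrument-strength statistics
  (per-SNP F = (β/SE)², R² = F/(n−2+F); overall F = ((n−k−1)/k)·R²/(1−R²)).
- **`mrpipe.estimators`** — Wald ratio, inverse-variance-weighted MR with
  multiplicative random effects (the primary method), MR-Egger with the
  directional-pleiotropy intercept, weighted-median MR with a seeded
  parametric-bootstrap SE, MR-PRESSO (global, outlier and distortion tests),
  and odds-ratio reporting with per-unit-decrease sign handling.
- **`mrpipe.mvmr`** — multivariable IVW (direct effects conditional on
  co-exposures), conditional F-statistics, and step-wise mediation
  (total-effect screen → exposure–mediator screen → MVMR direct effect;
  attenuation is reported qualitatively, the indirect effect and proportion
  mediated are deliberately not computed).
- **`mrpipe.synthetic_data`** — seeded generator of two-sample summary
  statistics with known ground truth: causal, pleiotropic (InSIDE or not)
  and mediated architectures, LD blocks, binary-outcome log-OR scaling, and
  representational corruption (strand flips, allele swaps, palindromes) for
  harmonization tests.
- **`mrpipe.pipeline`** — YAML-config-driven study orchestration: primary
  analyses with Bonferroni (0.0125) and nominal (0.05) significance flags,
  the sensitivity suite, bidirectional MR, covariate-adjusted (MVMR)
  analyses, mediation, a per-pair instrument audit, and a reproducibility
  manifest.

## CLI

```sh
# write a synthetic dataset (exposure/outcome[/mediator]/ld/truth TSVs)
mrpipe simulate --preset births_like --seed 7 --out data/

# run analyses from a YAML config
mrpipe mr            --config study.yaml --out results/
mrpipe sensitivity   --config study.yaml --out results/
mrpipe bidirectional --config study.yaml --out results/
mrpipe adjust        --config study.yaml --out results/
mrpipe mediate       --config study.yaml --out results/
mrpipe report        --config study.yaml --out results/   # everything
```

Minimal config:

```yaml
tables:
  afb: {path: data/exposure.tsv, units: year, per_unit_decrease: true}
  cad: {path: data/outcome.tsv, binary: true}
  bmi: {path: data/mediator.tsv}
exposures: [afb]
outcomes: [cad]
mediators: [bmi]
ld: data/ld.tsv
seed: 1
```

Identical config + seed reproduces byte-identical outputs; every run writes
`manifest.json` (config hash, seed, library versions).

## File formats

GWAS tables are TSV with columns `snp, effect_allele, other_allele, eaf,
beta, se, pval, n, n_case, n_control` (`eaf`/`n_case`/`n_control` optional;
arbitrary source headers can be mapped via `column_map`). LD tables are
long-format TSV `snp_a, snp_b, r2`; absent pairs default to r² = 0.
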