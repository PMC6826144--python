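# telomr

Mendelian randomization (MR) of genetically determined leukocyte telomere
length against aging-related outcomes, as a reusable, tested pipeline:

- **`telomr.panel`** — instrument-panel I/O and validation (13-SNP fixture
  panel with an r² LD matrix), √r² correlation handling with PSD repair,
  perfect-LD pruning, and all unit conversions between SD of telomere
  length (≈650 bp), base pairs, and years of adult attrition (≈25 bp/year;
  250 bp ≈ one decade).
- **`telomr.simulate`** — synthetic biobank-style cohorts: LD-correlated
  genotype dosages via a calibrated Gaussian copula (HWE per SNP), a latent
  standardized exposure explaining a target R² (2.23% by default), logistic
  binary outcomes calibrated to a marginal prevalence, continuous outcomes,
  parental attained ages, and raw survey/measurement fields.
- **`telomr.phenotypes`** — outcome derivations: early-death cutoffs
  (KDE-mode minus half-normal SD), parental-lifespan z-score, top-decile
  and near-centenarian parental survival contrasts, 49/47-item frailty
  index with log(x+1), cognitive transforms, EWGSOP sarcopenia, Fried
  frailty, and survey codings (depression, pains, falls).
- **`telomr.assoc`** — per-SNP association scans: OLS for standardized
  continuous outcomes, logistic IRLS for binary outcomes, covariate
  adjustment, age/sex strata, plus fast vectorized marginal scans.
- **`telomr.mr`** — correlated-instrument MR: IVW (fixed/random), the
  likelihood-based estimator, MR-Egger with intercept pleiotropy test,
  Benjamini–Hochberg FDR, and per-250bp report finalization.
- **`telomr.power`** — analytic MR power (normal approximation) for binary
  and continuous outcomes with the <80% low-power flag.
- **`telomr.pipeline` / `telomr.cli`** — orchestration with plain-text
  artifacts and a JSON run manifest.

## CLI

```bash
telomr simulate --n 50000 --seed 7 --out cohort.tsv
telomr derive   --cohort cohort.tsv --out outcomes.tsv
telomr assoc    --cohort cohort.tsv --stratum "60+/all" --out assoc.tsv
telomr mr       --assoc assoc.tsv --out mr.tsv
telomr power    --table sizes.tsv --out power.tsv
telomr all      --n 20000 --seed 1 --out runs/demo
```

`telomr all` writes `cohort.tsv`, `derived_outcomes.tsv`, `assoc.tsv`,
`mr_results.tsv`, `egger_scatter.tsv`, `power.tsv`, `forest.tsv` and
`manifest.json` into the output directory. Identical config + seed gives
byte-identical outputs. Options can also come from a YAML config
(`--config`); see `telomr.pipeline.DEFAULT_CONFIG` for the keys.

## Notes

- The shipped 13-SNP panel (`telomr/data/panel_13snp.tsv`) carries
  synthetic placeholder betas/SEs/frequencies calibrated so the
  uncorrelated variance explained totals 2.23%; they are not transcriptions
  of any published supplement. Real instrument tables in the same
  tab-separated layout can be swapped in via `--config`.
- All simulation stages derive their RNG streams from one master seed with
  fixed per-stage offsets, so results are bit-reproducible.
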