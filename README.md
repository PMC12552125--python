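# lipidkit

Quantitative shotgun-lipidomics analysis as a tested, reusable pipeline:
from species-level concentration tables (targeted Lipidyzer/SLA-style
output) through blank filtering, normalization, class aggregation,
double-bond saturation profiling and differential lipotype statistics.
A synthetic lipidome generator stands in for real cell-pellet data, so
every stage is testable fully offline.

## What it does

- **nomenclature** — parse and canonicalize lipid species names in
  shorthand notation (`CE 18:1`, `PC 16:0/20:4`, `TG 16:0_18:1_18:2`),
  with a fixed 16-class registry (CE, CER, DCER, HCER, LCER, DG, FFA,
  LPC, LPE, PC, PE, PG, PI, PS, SM, TG), synonym mapping (TAG→TG,
  LacCER→LCER, ...) and sum-composition arithmetic.
- **io** — read wide CSV/TSV concentration tables and metadata sheets,
  validate them mechanically, and assemble a canonical dataset bundle
  (order-independent, bit-stable on re-write). Zeros are measured zeros;
  only ``""``/``NA``/``NaN`` are missing. No imputation anywhere.
- **blank_filter** — species must reach 2× the blank background in ≥80%
  of biological samples; globally failing species are reintroduced when
  they reach it in ≥60% of the samples of a single experimental group
  (groups = concatenation of all grouping variables). All parameters are
  configurable; defaults reproduce that rule exactly.
- **quantify** — class totals, percent-of-total normalization (class and
  species level share one denominator), row z-scores, and per-sample /
  per-group log2 fold changes against a control group.
- **saturation** — abundance binned by total double bonds for TG, CE or
  the pooled glycerophospholipid classes (PC, PE, PG, PI, PS, LPC, LPE;
  SM optional), normalized over total lipid, fold change vs the control
  mean.
- **stats** — two-group differential testing on percent-of-total values
  (Shapiro–Wilk-gated t / Mann–Whitney, paired variants, optional
  experiment-mean aggregation), Benjamini–Hochberg correction per family
  (classes and species separately), and PCA lipotype analysis.
- **synthetic** — cell-type lipotype templates (iNeuron / iAstrocyte /
  iMicroglia) over a >1,000-species synthetic roster, log-normal noise,
  blank background, and injectable effect signatures (`apoe4`,
  `reactive`, `cholesterol_load`). All template fractions and effect
  sizes are synthetic parameters, not measurements.

## CLI

```sh
# generate a synthetic bundle (matrix + metadata + manifest)
lipidkit simulate --out sim/ --seed 1 --template iAstrocyte \
    --groups "control:6,case:6" --effect case:apoe4

# sanity-check inputs
lipidkit validate --matrix sim/concentrations.csv --metadata sim/samples.csv

# full pipeline: validate -> filter -> quantify -> saturation -> stats
lipidkit analyze --matrix sim/concentrations.csv --metadata sim/samples.csv \
    --control-group control --out results/

# individual stages and a markdown summary
lipidkit filter --matrix ... --metadata ... --out filtered/
lipidkit saturation --matrix ... --metadata ... --control-group control \
    --pool TG --pool phospholipids --out sat/
lipidkit report --results results/
```

`analyze` also accepts a YAML config (`--config run.yaml`) mirroring
`lipidkit.pipeline.PipelineConfig`; command-line flags override the file.
Every run writes its effective config, a JSON stage log and volcano-ready
CSV payloads (filter report, class/species percent matrices, z-scores,
fold-change matrices, saturation profiles, differential results, PCA
scores/loadings) into the output directory.

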