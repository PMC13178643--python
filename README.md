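# stimpd

Analysis toolkit for sex- and hormone-dependent stimulant pharmacodynamics,
covering three data modalities end to end:

- **FSCV kinetics** (`stimpd.fscv`): fits a pulsed-release / saturable-clearance
  model (dC/dt = −Vmax·C/(Km + C) with instantaneous release per stimulus
  pulse) to evoked dopamine transients, derives the apparent Michaelis
  constant at each uptake-inhibitor concentration, and estimates drug potency
  as Ki = baseline Km / slope of the apparent-Km vs concentration regression.
- **Transcriptomics** (`stimpd.transcriptomics`): single-nucleus count QC
  (min-genes, min-cells, 98th-percentile, mitochondrial-fraction rules),
  CPM-style log1p normalization, marker-coexpression projection classification
  (Calb1∧Sox6 → core, Calb1∧Aldh1a1 → shell), and a balanced-bootstrap DEG
  counting procedure (resample 30 nuclei per sex with replacement, 50
  iterations, Wilcoxon rank-sum per gene, |log2FC| > 0.5 and BH-adjusted
  p < 0.025) compared across regions with a Mann-Whitney U test.
- **Behavior** (`stimpd.behavior`): vigilance-session scoring — hit /
  false-alarm rates, d′ = z(hit) − z(FA) with extreme-rate clamping,
  3-session baselines with a 30% stability gate, and percent-change
  dose–response assembly.

Each stage is paired with a seeded synthetic generator (`stimpd.synthetic`)
that is the explicit forward model of the corresponding analysis, so every
estimator can be validated against known ground truth. `stimpd.stats`
provides the shared, oracle-verified primitives (exact/normal Mann-Whitney,
Benjamini-Hochberg, OLS, a <1e-9-accurate inverse normal CDF).

## CLI

All functionality is exposed through the `stimpd` entry point:

```sh
stimpd simulate-fscv --out trace.csv --seed 1 --inhibitor-conc 3.0
stimpd fit-fscv --trace trace.csv --float dap,km
stimpd potency --series traces/ --out potency.json

stimpd simulate-counts --out mtx/ --seed 1
stimpd classify --counts mtx/
stimpd deg-bootstrap --counts mtx/ --region core --seed 7 --out core.json
stimpd compare-regions --core core.json --shell shell.json

stimpd simulate-behavior --out session.tsv --seed 1
stimpd score-behavior --log session.tsv
stimpd dose-response --sessions sessions/

stimpd run-demo --out demo/ --seed 11       # all three stages + manifest
stimpd validate trace.csv mtx/ session.tsv  # format diagnostics
```

`run-demo` is deterministic: the same seed produces byte-identical report
bundles. A YAML config (strict schema, see `stimpd.pipeline.RunConfig`) can
override any stage's parameters.

## Data formats

- Traces: CSV `time_s,value,unit` (+ JSON sidecar with protocol/condition).
- Counts: MatrixMarket triplet (`matrix.mtx`, `genes.tsv`, `barcodes.tsv`)
  plus `metadata.tsv` (nucleus_id, sex, sample, truth labels).
- Event logs: TSV `t_s\tevent\tport` with a mandatory header.
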