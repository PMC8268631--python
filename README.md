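# cartograph

Self-organizing-map (SOM) molecular cartography of paired bulk
gene-expression and promoter-methylation cohorts.

Tumor cohorts such as diffuse gliomas split into molecular subtypes
whose differences are carried by modules of co-regulated genes and by
genome-wide promoter methylation patterns (e.g. the CpG-island
methylator phenotype of IDH-mutant tumors). `cartograph` is for
computational biologists who want to *see* that structure: it trains a
SOM on the gene × sample matrix so that every sample becomes a square
"portrait" of metagene activity, then derives from the trained map

- **spot modules** — connected map regions of concerted overexpression
  (or hypermethylation), i.e. data-driven gene modules with per-sample
  profiles, binary calls, and co-occurrence ("implication") statistics;
- **gene-set views** — GSZ scores (a set-sum z-score under exact
  without-replacement sampling moments) and gene-set density maps;
- **phenotype maps** — per-unit Cox log hazard ratios (Breslow partial
  likelihood, per-SD covariate), Kaplan–Meier/log-rank for sample
  groups, Pearson maps for continuous covariates (age, telomere-length
  ratio), and a "female difference score" map;
- **expression–methylation integration** — per-unit covariance maps and
  a network joining expression spots to methylation spots with
  significant gene overlap (one-sided Fisher, p < 10⁻³) and
  anti-correlated profiles, exposing the cohort's coupled regulatory
  modes.

A synthetic cohort generator with planted ground truth (subtypes,
modules, methylation coupling, survival hazards) backs every stage with
recovery tests; real cohorts enter through plain TSV/CSV/GMT files.

## The core model

Genes are points in sample space. A batch SOM with grid_k² units
(50×50 for expression, 30×30 for methylation by default) alternates
BMU assignment with Gaussian-neighborhood-weighted codebook updates,
the radius annealing linearly from grid_k/2 to 0.5 and then freezing,
so the quantization error settles monotonically. A sample's portrait
is its codebook column reshaped to the grid; group means and pixel-wise
differences compare subtypes. Spots are 8-connected components above
the nearest-rank 0.98 quantile; the pipeline's group-resolved variant
applies that threshold to each group-mean portrait so adjacent modules
of different subtypes stay separate. See `docs/methods.md` for the
full model, parameter and limitation account.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/06_em_network.py` generates a 1,500-gene, 60-sample
cohort with four planted modules (two methylation-coupled), trains both
maps, and prints:

```
module 0 (coupled  ): mean unit covariance -0.0553
module 1 (coupled  ): mean unit covariance -0.0552
module 2 (uncoupled): mean unit covariance +0.0004
module 3 (uncoupled): mean unit covariance +0.0001
-> coupled modules are negative (methylation suppresses expression); uncoupled sit at zero.
edge E:A -- M:A: overlap 30, p = 1.9e-63, profile r = -0.99
...
```

The negative covariances are the planted coupling slope (−0.3 beta per
log10 unit) times the activity variance; the network edge links the
coupled module's expression spot to its methylation spot.

A full run (simulate → preprocess → train E/M → spots → gene sets →
phenotype maps → integration, with a manifest and byte-reproducible
outputs) goes through one YAML config:

```bash
cartograph run --config my_run.yaml --seed 17
```

or `run_pipeline(RunConfig(...))` from Python. Subcommands
(`simulate`, `train`, `spots`, `genesets`, `phenomap`, `integrate`)
expose the individual stages.

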