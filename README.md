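# regulonkit

A toolkit for inferring a sigma-factor regulon from expression kinetics and
ChIP peak data:

* **Kinetic models** (`regulonkit.kinetic_models`) — three transcription
  models of increasing complexity for a target mRNA x(t):
  constant synthesis (`dx/dt = k1 − k2·x`), direct regulation
  (`dx/dt = k1·σ(w·y + b) − k2·x` with y the regulator), and cooperative
  regulation, where y is the concentration of a regulator–cofactor
  equilibrium complex.  The complex level is the smaller root of
  `y² − (yA + yB + q)·y + yA·yB = 0`, evaluated in a cancellation-free form;
  it interpolates between `min(yA, yB)` (q → 0) and 0 (q → ∞).
* **Expression preprocessing** (`regulonkit.expression_data`) — de-logging,
  per-timepoint mean normalization, and least-squares piecewise-cubic
  smoothing with four interior anchor points.
* **Model fitting** (`regulonkit.model_fitting`) — bounded simulated
  annealing with data-informed restarts and local polish, minimizing rmse
  against the smoothed target (a MAP estimate under a uniform prior); a
  model-selection cascade (constitutive / regulated / complex-only /
  not-modeled, with 10 % / 20 % improvement tiers); and a false-positive
  estimate that permutes the regulator series, refits every target, and
  filters accepted fits whose weight |w| < 1e-4 ("no control").
* **Regulon mapping** (`regulonkit.regulon_mapping`) — peak filtering
  (P < 0.05, fold enrichment ≥ 2), strand-aware assignment of peak summits
  within 300 bp upstream of annotated start codons, and operon expansion.
* **Promoter analysis** (`regulonkit.promoter_analysis`) — TSS-anchored
  window extraction, TANNNT / PWM motif anchoring with exact enumeration
  P-values, −14/−13 GG classification, genome-wide overlapping-GG
  background (`f_GG = count(GG) / (len − 1)`), expected counts
  (`N = f_GG · n_sites`), and Fisher exact enrichment.
* **Synthetic data** (`regulonkit.synthetic_data`) — deterministic
  generators for every input (expression series from known kinetic
  parameters, a genome with planted promoters/peaks/operons) with full
  truth tables.
* **Reporting** (`regulonkit.reporting`) — pipeline orchestration, category
  partition summaries, and functional-category fold abundance
  `(k/K) / (m/N)`.

## CLI

All stages are exposed under a single `regulon` entry point:

```sh
regulon simulate --outdir sim --seed 1          # synthetic input bundle
regulon preprocess --in expr.tsv --log2 --out norm.tsv --smooth-out smooth.tsv
regulon simulate-model --params params.json --times 0,1,2
regulon fit --expression sim/expression.tsv --out fits.tsv
regulon fpr --expression sim/expression.tsv --n 20 --seed 1 --out fpr.tsv
regulon annotate-peaks --peaks sim/peaks.tsv --genes sim/genes.gff3 \
    --operons sim/operons.tsv --out regulon.tsv
regulon promoter-stats --genome sim/genome.fa --tss sim/tss.tsv --out stats
regulon run --config run.cfg                    # full pipeline
```

`run.cfg` is a flat `key = value` file (see `regulonkit.reporting.RunConfig`
for the keys).

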