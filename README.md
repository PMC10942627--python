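# cfflux

Mass-balance accounting of plasma cell-free DNA (cfDNA) against cellular
turnover, with full multiplicative-uncertainty propagation.

## The problem

The human body replaces on the order of 10¹¹ cells per day. If all the DNA
of dying cells reached the bloodstream and cleared with the measured cfDNA
half-life, plasma would carry vastly more cfDNA than the ~1000 genome
equivalents (GE) per ml actually observed. `cfflux` quantifies that gap per
cell type: it converts turnover rates into the *potential* cfDNA
concentration, compares it with the *measured* concentration apportioned by
methylome deconvolution, and reports the **capture ratio** — the fraction of
dying-cell DNA that appears as plasma cfDNA — with 95% confidence intervals.
It is aimed at researchers working on liquid biopsy sensitivity, cfDNA
biology, and quantitative physiology.

## The model

For a cell type with turnover `d_c` (cells/day) and ploidy `p_c` (haploid
genome sets per dying cell), the potential plasma concentration is

    X_c = d_c · p_c · τ / V_plasma        [GE/ml]

with mean cfDNA lifetime `τ = half-life / ln 2 = 0.7 h` and plasma volume
`V_plasma = 3 L`. Multiplication by the haploid genome mass
`m_h = 3.2·10⁻¹² g` converts GE/ml to g/ml.

Every input is carried as a median with a multiplication error factor
`f ≥ 1` (a lognormal with shape `s = ln f`; `f = 2` means a 68% chance the
true value is between half and double). Products and ratios propagate
exactly via `f_xy = exp(√(ln²f_x + ln²f_y))`; sums and the
ultrashort-fragment correction (a uniform 1–2 multiplier on the total
concentration, midpoint 1.5) propagate by seeded bootstrap followed by a
lognormal refit.

## Worked example

```bash
cfflux compute \
    --celltypes src/cfflux/data/celltypes_synthetic.csv \
    --out results/demo --seed 1
```

writes `results/demo.csv`, `results/demo.json` and a run manifest. Key rows
of the results table (values printed by the command above):

| cell type | potential (GE/ml) | measured (GE/ml) | capture ratio |
|---|---|---|---|
| erythrocyte_progenitors | 3.89e+06 | 131 | 3.38e-05 (≈1:30,000) |
| neutrophils | 1.75e+06 | 467 | 2.67e-04 |
| megakaryocytes | 1.15e+04 | 380 | 0.033 (≈1:30) |
| endothelial_cells | 3.89e+03 | 129 | 0.033 (≈1:30) |
| pancreatic_beta_cells | 0.583 | — | below detection |

Reading: even the best-captured cell types deliver only ~3% of their
dying-cell DNA to plasma, and the capture ratios span roughly three orders
of magnitude (≈978-fold on this table) — erythroid progenitors, whose
extruded nuclei are engulfed within erythroblastic islands, release only
~1 part in 30,000. Externally shed epithelia (gut, lung, kidney, bladder,
skin) have no measured entry: their dying cells leave the body. The
`detection` column classifies each potential concentration against assay
sensitivity (~10 GE/ml for genome-wide deconvolution, ~1 GE/ml for targeted
marker assays).

The packaged table `celltypes_synthetic.csv` is a synthetic reconstruction
of a healthy-adult cell-type table (see `cfflux/datasets.py`); you can
substitute any CSV with the same columns.

A parameter-recovery study over synthetic cohorts:

```bash
cfflux simulate --replicates 200 --noise-factor 1.5 --seed 3 --out results/sim
# coverage=0.947 mean_log_bias=+0.0130 -> results/sim.recovery.csv
```

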