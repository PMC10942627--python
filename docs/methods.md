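# Methods

## Model

`cfflux` treats plasma cfDNA as the steady state of a one-compartment mass
balance. Cells of type *c* die at rate `d_c` (cells/day), each releasing
`p_c` haploid genome copies. If all of that DNA entered plasma and cleared
exponentially with mean lifetime `τ`, the standing concentration would be

    X_c = d_c · p_c · τ / V_plasma    [genome equivalents / ml]

— intuitively, the DNA of the cells that died during one clearance lifetime,
diluted into the plasma volume. The measured concentration for the same cell
type is the total plasma cfDNA concentration, corrected for assay-invisible
ultrashort fragments, times the cell type's methylome-deconvolution
fraction. The capture ratio (measured / potential) is the fraction of
dying-cell DNA that appears as measurable plasma cfDNA. Inverting the same
balance against a measured concentration gives the clearance half-life that
a purely systemic-clearance explanation would require; values of seconds or
less argue that most dying-cell DNA never enters the blood at all.

Assumptions: steady state (healthy homeostatic turnover, no acute injury);
a single well-mixed plasma compartment; one clearance lifetime shared by all
cell types; deconvolution fractions that refer to the same material as the
total-concentration measurement; and independence of all uncertain inputs.

## Uncertainty propagation

Every uncertain quantity is a median plus a multiplication error factor
`f ≥ 1`, i.e. a lognormal with shape `s = ln f`. This representation is
closed under products and ratios (`f_xy = exp(√(ln²f_x + ln²f_y))`, the
root-sum-square rule on log-shapes, valid for independent operands) and
turns 95% confidence intervals into `median · exp(±1.96 s)`. Reported
intervals that arrive as 95% CIs are converted by
`s = ln(hi/lo) / (2·1.96)`: asymmetric intervals are symmetrized on the log
scale and the stated median kept.

Two operations have no closed form and use seeded Monte Carlo:

* **Sums** (e.g. hepatocyte ploidy-class fluxes): joint draws are summed per
  iteration and a lognormal refitted; 1000 iterations by default.
* **The ultrashort-fragment adjustment**: single-strand ~50 bp fragments
  escape standard libraries but carry a comparable molar amount of DNA, so
  the total concentration is multiplied by a factor known only to lie in
  [1, 2] (expected value 1.5). Each of 10,000 iterations multiplies a draw
  of the total by a uniform draw of the factor, then a lognormal is
  refitted. A degenerate range (`low == high`) is applied exactly, without
  sampling. Note the refit reports the geometric-mean multiplier
  exp(E ln U) ≈ 1.4715 rather than the arithmetic mean 1.5 — a ~2%
  difference that is far inside every factor in the budget.

The lognormal refit uses the log-scale mean and *population* standard
deviation (`median = exp(mean ln x)`, `factor = exp(sd ln x)`), so that
fitting exactly inverts sampling from the model in the large-n limit and is
insensitive to the heavy right tail. No covariance terms are carried:
quantities are propagated as independent throughout.

All stochastic operations take an explicit seed; pipeline-level seeds derive
per-operation seeds through `numpy.random.SeedSequence`, making every output
bitwise reproducible from the run manifest.

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| plasma volume `V_plasma` | 3 | L | reference adult; treated as exact |
| mean cfDNA lifetime `τ` | 0.7 (f = 1.70) | h | half-life/ln 2 ≈ 29 min; factor from the 15–120 min literature half-life range read as a ~95% interval |
| haploid genome mass `m_h` | 3.2e-12 | g | converts GE/ml to g/ml; exact |
| total plasma cfDNA | 1000 (f = 1.45) | GE/ml | healthy-cohort median; factor combines the median's CI (f≈1.08) with inter-individual/analytical variation (f = 1.44) |
| adjustment range | [1, 2] | — | ultrashort-fragment correction; midpoint 1.5 |
| detection band | [1, 10] | GE/ml | targeted marker assays (~0.1% of total) to genome-wide deconvolution (~1%) |
| bootstrap iterations | 1000 (sums), 10,000 (adjustment) | — | configurable |

After the adjustment, the total-concentration factor is ≈1.52 — an
uncertainty budget comfortably below a factor of 3, too small to affect
order-of-magnitude conclusions.

Internally everything is evaluated in days and millilitres; hours and litres
are converted at the module boundary.

## Bespoke turnover estimators

* **Megakaryocytes** are estimated two ways — marrow census / maturation
  time (~5 days), and platelet production / platelets per megakaryocyte —
  and merged by `combine_estimates`: geometric-mean median, factor the
  larger of the within-estimate factors and the between-estimate spread
  `√(larger/smaller)`, so method disagreement widens rather than narrows the
  result. Megakaryocytes are polyploid; their ploidy (~16N) is a table
  input, not a constant.
* **Hepatocytes** are combined across ploidy classes: the turnover median is
  the summed death flux `Σ countᵢ·rateᵢ`, the effective ploidy is the
  death-flux-weighted mean ploidy (treated as exact), and a per-group factor
  propagates through the bootstrap sum.

## Detection classification

Potential concentrations are classified against the sensitivity band on the
median: ≥10 GE/ml is detectable by genome-wide deconvolution, [1, 10) only
by targeted assays, <1 below current assays. The limit is a gradient across
assay designs, so the classifier reports where the point estimate falls
rather than intersecting intervals with the band.

## Reference table

The packaged `celltypes_synthetic.csv` is a synthetic reconstruction of a
healthy-adult cell-type table (turnovers at published orders of magnitude,
deconvolution-style fractions summing to ≤1, spread factors typical of the
source literature); see `cfflux/datasets.py`. It reproduces the headline
summaries — maximum capture ≈3.3%, extremes ≈1:30 (megakaryocytes,
endothelium) and ≈1:29,000 (erythroid progenitors), fold-range ≈978 — but
individual rows are rounded stand-ins, not measurements.

## Synthetic cohorts and what passing tests show

`generate_cohort` draws true turnovers log-uniformly in 1e9–3e11 cells/day
and true capture fractions log-uniformly in 3e-5–3e-2 (the observed regime
spans orders of magnitude, so log-uniform, not uniform), derives the implied
measured concentrations and total, and perturbs every observed quantity —
turnover, deconvolution fraction, total — with independent lognormal noise
of a stated factor (default 1.5, typical of the real inputs). The observed
total equals the sum of per-type contributions up to that noise; if noisy
fractions sum above 1 they are renormalized with the total scaled inversely,
leaving every total×fraction product unchanged.

Because the generator's noise model is exactly the pipeline's uncertainty
model, capture-ratio 95% CIs should achieve nominal coverage, and
`recovery_report` confirms ≈95% empirical coverage with negligible log-scale
bias over 500 replicates. That validates the propagation arithmetic — it
does **not** validate the model against real data: real inputs have
correlated errors (shared atlases and cohorts), possibly non-lognormal
tails, deconvolution biases near the detection limit, and age/sex structure,
none of which the generator emulates. The generator also produces input
tables only — no sequencing reads, methylation patterns, or fragmentomics.

## Numerical choices

* Degenerate inputs: zero-width intervals fit factor 1; `low == high`
  adjustment ranges multiply exactly; single-element sums reduce to the
  element up to Monte-Carlo error.
* `divide(x, x)` has median 1 but factor >1 — operands are always treated as
  independent.
* Detection thresholds and ratio summaries (fold-range, maximum capture) use
  medians; CIs are reported alongside, matching how the results are quoted
  (reciprocals rounded to one significant figure).
* Problem sizes: self-consistency checks use 1e6 direct draws; the
  adjustment-midpoint check 1e5 iterations; coverage studies 500 replicates
  of 8-type cohorts. These give Monte-Carlo errors well under the 1–2%
  tolerances asserted.
* CSV round-tripping uses shortest-roundtrip float formatting on write and
  `float_precision="round_trip"` on read, so `load(save(x)) == x` exactly.

## Limitations

Single-compartment clearance (no liver/kidney-specific removal, no DNase
kinetics); healthy young-adult reference values only — ratios in elderly or
diseased cohorts may differ through both turnover and deconvolution inputs;
cfDNA release from living cells (e.g. NETosis) is not modelled and would
shift the attribution, not the mass balance; cell types below current
deconvolution sensitivity contribute to the potential side only and are
never imputed a ratio.
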