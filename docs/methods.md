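# Methods

## The experiment and its dataset

The package models a three-level full factorial extraction experiment on
Turkey-oak wood chips. Factors and levels (natural units):

| factor        | low | mid | high | units |
|---------------|----:|----:|-----:|-------|
| temperature   |  20 |  50 |   80 | °C    |
| ethanol       |   0 |  20 |   40 | % v/v |
| time          |   3 |   6 |   24 | h     |

All 27 level combinations were run once (response values are means of
triplicate assays); responses are extraction yield (%), DPPH and FRAP
antioxidant capacity (mg TE/g), total phenolics (mg GAE/g), total flavonoids
(mg QE/g) and condensed/hydrolyzable tannins (mg TAE/g). The packaged CSV
(`extractopt/data/turkey_oak_runs.csv`) stores the published run means and
standard deviations. Three DPPH/FRAP cells are printed with different
rounding in the source's run table and its model-comparison table; the
package carries the comparison-table values, which are the only ones
consistent with the published grand means (e.g. DPPH mean 215.54) and error
metrics. Replicate-level raw data are not published, so everything operates
on run means; in particular the Pearson correlation analysis uses the 27
means, which reproduces the published correlation table to the printed
precision.

## Variable coding

Factors are coded as `X = (x − (low+high)/2) / ((high−low)/2)`, so the low
and high levels map to ±1 exactly. Because the time levels are asymmetric,
the 6 h mid level codes to −5/7 ≈ −0.714, not 0 — the design's nominal
"(0)" label for 6 h is only a label. This choice is forced by internal
consistency: only midpoint/half-range coding reproduces the published
regression intercepts and every published model prediction. Coded values
are kept at full floating precision. The temperature low level is 20 °C
throughout (one table in the source prints 25 °C, but the dataset and all
derived quantities use 20 °C).

## Factorial regression

Each response is fitted by OLS (statsmodels, QR-based) to the 8-term model
(intercept, 3 mains, 3 two-way products, the three-way product) on coded
factors, giving 19 residual df on 27 runs. No response transformation is
applied. Per-term SEs are `sqrt(MSE · diag((X'X)⁻¹))` with two-sided t
tests; p-values are reported at full precision and displayed to 4 decimals.

Diagnostics:

* `R² = 1 − SSE/SST`, `adj R² = 1 − (1−R²)(n−1)/(n−p)`;
* `PRESS = Σ (eᵢ/(1−hᵢᵢ))²` (leverage shortcut — exact leave-one-out for
  OLS, no refit loop), `pred R² = 1 − PRESS/SST`;
* adequate precision `= (max ŷ − min ŷ)/sqrt(p·MSE/n)`; the
  response-surface-software convention, adopted because it is the definition
  consistent with the published diagnostic values; > 4 is the usual
  usability floor;
* `CV% = 100·sqrt(MSE)/ȳ`.

A model is flagged **inadequate** when its predicted R² is negative or its
adequate precision is ≤ 4; on this dataset that excludes the condensed-tannin
(CTC) model from optimization, as in the original analysis. Predictions at
arbitrary settings carry `SE_fit = sqrt(x'(X'X)⁻¹x·MSE)` and a 95 %
prediction interval for a *new single observation*,
`fit ± t(0.975, df)·sqrt(MSE + SE_fit²)` — the new-observation form is what
reproduces the published interval half-widths. Points outside the factor
cube are predicted but flagged as extrapolations.

## Desirability optimization

Only larger-is-better goals are implemented (the study maximizes every
response). Per response, `d = clip(((y−L)/(T−L))^w, 0, 1)`; unless the user
overrides them, `L`/`T` are the observed minimum/maximum of that response in
the dataset and `w = 1` — the only convention under which the published
composite desirabilities (0.95 for the three-response optimum, 1.000 for the
DPPH-only optimum) are recovered. Predictions above `T` are capped at
`d = 1`, so a model extrapolating beyond the observed maximum stays
feasible. Composite desirability is the geometric mean.

The optimizer screens an 11³ grid over the coded cube, refines the 20 best
grid points with Nelder–Mead (arguments clamped to the cube, 1e−6 coordinate
tolerance) and returns the best point; exact ties go to the
lexicographically smallest coded coordinates so results are reproducible.
The time direction is nearly flat for DPPH/FRAP, so "interior-time" optima
reported by other optimizers differ from the cube corner by negligible
amounts of D; the package reports D to 4 decimals precisely so such flat
ridges are visible, and makes no attempt to match any particular interior
coordinate.

## Neural model

Architecture: 3 inputs → H hidden → 3 outputs, logistic sigmoid on both
layers (the sigmoid *output* layer forces bounded targets, hence min–max
scaling of inputs and targets to [0.1, 0.9]; the margin keeps the observed
extremes off the saturated tails). Defaults follow the study where it
specifies them — H = 10 (with a topology search over 8–12), 70/15/15
train/validation/test split (19/4/4 runs on n = 27), DPPH/FRAP/TPC as joint
targets — and otherwise use the standard Levenberg–Marquardt settings of
that algorithm's reference implementation: μ₀ = 1e−3, ×10 on a rejected
step, ×0.1 on an accepted one, max 1000 epochs, early-stopping patience 6.
Weights initialize uniformly in [−0.5, 0.5]. The split membership and
initialization are drawn from a seeded generator; the original study's split
is unknown, so reproduction claims about training quality are made over
seeds (best-of-20), not per-seed.

Each epoch solves `(J'J + μI)δ = J'e` on the training subset, with `J` the
analytically backpropagated Jacobian of the residuals (verified against
finite differences to 1e−6 in the tests). Validation MSE is recorded every
epoch and the weights at its minimum are the ones returned. If μ saturates
(> 1e10) after at least one accepted step, training has converged and stops;
a saturation before *any* accepted step raises `TrainingFailure` with the
history attached. When the validation split is empty the stopping criterion
falls back to training MSE.

The original network's weights are not published, so its exact per-run
predictions cannot be regenerated; they are shipped as a data file
(`ann_predictions_reference.csv`) and used by the comparison stage, while
the trainer itself is validated structurally (identity-activation LM
converges to the OLS solution; zero-noise linear data are fit below 1e−3
scaled MSE; early stopping always returns the min-validation weights).

## Model comparison

MAE, RMSE and `R² = 1 − Σ(Ŷ−Y)²/Σ(Ȳ−Y)²` with `Ȳ` the experimental mean —
not a regression of predicted on experimental, so R² can be negative. The
report emits the 27-row experimental/factorial/neural value table plus the
3-metric × 2-model table per response.

## Synthetic data

`generate` draws `y = Xb + q·(X1² − mean X1²) + ε`, `ε ~ N(0, σ²)` i.i.d.
over the design: a linear-plus-interaction truth, optional pure-quadratic
curvature on the first factor (centred so the intercept is untouched), and
homoscedastic Gaussian noise on run means. Defaults mirror the study
conditions: the published DPPH coefficient vector as truth and σ = 48.41
(the DPPH residual SD). Replicate-level noise can be emulated with σ/√3.
The generator reproduces the *statistical* structure assumed by the
regression stage only — it has no extraction kinetics, no heteroscedasticity
and no assay-specific error structure, so passing recovery tests validates
the estimation machinery, not the chemistry. Curvature is the lever for the
linear-vs-nonlinear contrast: the 8-term model cannot represent X1², so a
quadratic truth degrades its leave-one-out fit while the network can track
it (the suite checks the network wins on noiseless-truth MAE in ≥ 8/10
seeds at q = 60, σ = 8 — curvature comparable to the main effects, noise
well below signal).

`recovery_experiment` repeats generate→fit and reports per-term bias and
95 % CI coverage of the truth (≈ 0.95 under a linear truth by construction).

## Problem sizes and numerics

All dataset computations run on the 27-run table in well under a second.
Stochastic checks use 2000 replicates for CI coverage, 20 seeds for the
best-of-seeds training correlation, and 10 generator seeds × 3 training
seeds for the nonlinearity contrast — sizes at which each check completes in
seconds while leaving Monte-Carlo error well inside the asserted bands.
Rank deficiency is detected at 1e−10 relative tolerance and raises rather
than silently pseudo-inverting. Optimizer determinism: all randomness
(simplex jitter, splits, inits, noise) flows from explicit integer seeds.

## Known limitations

* Tukey post-hoc letter groupings of the run table are out of scope —
  they need the unpublished replicate-level data.
* One fit-statistics row in the source (HTC) is internally inconsistent
  (its printed R² is below its adjusted R², and its first four entries
  duplicate another row); the package computes HTC diagnostics from the data
  and does not treat that printed row as a reference.
* Only maximize-type desirability goals exist; target-is-best and minimize
  variants, blocking, replication handling and second-order (quadratic)
  response-surface models are not implemented.
* The neural stage trains on 19 points; its validation/test correlations
  vary strongly across seeds, which is inherent to the data size, not a
  software defect.
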