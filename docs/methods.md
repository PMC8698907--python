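# Methods

## Regression model and solver

Each RTK response y (log2 expression over n samples) is regressed on
the design X of HDAC1–8 expression by minimising

    (1/2n)‖y − y₀ − Xω‖² + α·l1‖ω‖₁ + (α(1−l1)/2)‖ω‖₂²

The 1/(2n) loss scaling makes α comparable across cohort sizes and
matches the convention of the widely used coordinate-descent solvers,
which is what makes the library cross-check in the test suite a
meaningful equality (tolerance 1e-6) rather than a reparameterisation
exercise.

Predictors are standardised internally to mean 0 and unit (population)
variance before fitting. This matters twice: the penalty is
scale-sensitive, and the SCORE statistics compare squared coefficients
*across* HDAC genes, which is only meaningful on a common scale. Fitted
weights are reported on the original predictor scale (with the
intercept adjusted) for prediction; the standardised-scale weights are
kept on the model and are what enter SCORE and SCORE I.

The solver is cyclic coordinate descent on the p × p Gram matrix
(G = XᵀX/n, c = Xᵀy/n), so one coordinate update is O(p) regardless of
n. Each update is a soft-thresholding step
ω_j ← S(ρ_j, α·l1)/(G_jj + α(1−l1)). The objective value is recorded
after every sweep and is non-increasing by construction; the test suite
asserts this on every fit. Convergence is declared when the largest
absolute weight change in a sweep falls below `tol` (default 1e-6;
tests that compare against closed forms tighten this to 1e-12–1e-13),
with `max_iter` = 10,000 sweeps; non-convergence flags the model but is
not fatal. A zero-variance predictor is excluded with its weight pinned
at 0 and a warning. Degenerate inputs: a constant response yields zero
weights and intercept = mean(y); α large with l1 > 0 drives all weights
exactly to 0.

## Penalty selection

10-fold cross-validation over the grid α ∈ {0.001, 0.01, 0.1, 1, 10} ×
l1 ∈ {0.1, 0.5, 0.9} (both overridable). Folds are a seeded shuffle
followed by a contiguous split, so fold sizes differ by at most one and
the assignment is reproducible from the seed alone. The per-pair score
is the mean held-out MSE; ties break toward larger α, then larger l1,
preferring the sparser model. Each grid pair is evaluated
independently, so the order of the grid cannot influence selection.

Two selection modes exist because cohort-level analyses can reasonably
share one penalty pair across genes: `dataset` (default) averages the
CV error surface over all RTK responses and picks a single pair for the
cohort; `gene` picks a pair per RTK. A pinned pair can also be supplied
directly, which is how permutation nulls are refit cheaply at the
penalties selected on the unpermuted data.

## SCORE and ranking

SCORE = Σ ω̂ᵢ² over {HDAC1, 2, 3, 6, 8}; SCORE I = Σ ω̂ᵢ² over
{HDAC1, 2, 3, 8}, both on the standardised scale. Squaring makes
positive and negative dependencies contribute identically. Records are
ranked by SCORE descending with alphabetical tie-break (deterministic
output ordering); `top_k` takes the first k and `intersect_top` reports
the genes common to several lists in the order of the first. The
default predictor set is HDAC1–8 — the enzymes present in all the
motivating cohorts — and is configurable through the gene panel.

## Bliss synergy

Viability (% of untreated control) is converted to inhibition
f = clamp((100 − v)/100, 0, 1); viabilities above 100 (stimulation) are
retained in the matrix but clamp to inhibition 0, since Bliss
independence is defined on inhibition fractions. Single-agent
inhibitions are read from the zero-dose row/column; the excess at each
non-zero dose pair is 100·(f_obs − (fA + fB − fA·fB)) and the summary
score is the unweighted mean excess over those cells. No baseline
correction, outlier handling or surface smoothing is applied — the
score is the raw Bliss excess, a deliberate simplification relative to
full synergy suites whose correction settings vary between versions.
The classification threshold defaults to 10 (scores above it labelled
synergistic) and is exposed in the API and CLI.

## Dose–response and IC50

The 4PL v(d) = bottom + (top − bottom)/(1 + (d/ec50)^hill) is fitted by
bounded trust-region least squares, multi-started over hill ∈
{0.5, 1, 2, 4} with the best SSE retained. Bounds: top ∈ [80, 120]
(viability is relative to control), bottom ∈ [0, 100], hill ∈
[0.05, 20], ec50 within [min dose/10, max dose·10]. Viability is not
constrained to ≤ 100 during fitting. Two potency values are reported:
the absolute IC50 — the analytic crossing of the fitted curve with 50%
control viability, d = ec50·((top − 50)/(50 − bottom))^(1/hill) — and
the relative EC50 (curve midpoint). The absolute IC50 is primary
because viability is expressed relative to vehicle control; it is
flagged "not reached" when 50% lies outside (bottom, top) or the
crossing falls beyond 10× the largest measured dose. If no start
converges, a monotone PCHIP interpolation of the raw data on log-dose
supplies a fallback IC50; the same interpolated value is reported
alongside successful fits for comparison.

## ΔΔCt

Replicate Cts are averaged on the Ct scale before differencing (not as
a mean of fold changes), ΔCt is taken against GAPDH per condition, and
fold change is 2^(−ΔΔCt) with amplification efficiency fixed at 2. Two
identities pin the arithmetic: the reference gene against itself is
exactly 1, and swapping conditions inverts the fold change.

## Synthetic data: what it emulates, what it does not

`simulate_cohort` draws HDAC1–8 from a multivariate normal (default
mean 8.0 log2 units, unit variance, pairwise correlation 0.3 — HDAC
co-expression is plausible and 0.3 makes recovery non-trivial without
degenerate collinearity), plants RTK rows as y₀ + Xω + N(0, noise_sd)
and fills the remainder with independent N(8, 1) nulls. The default
recovery condition is n = 500 samples, 5 planted RTKs with weights
drawn uniformly in [1, 2] on HDAC1/2/3/8, 15 nulls, noise sd 0.5 —
sized like the motivating patient cohorts (N = 525 and 88) and tested
at both. Planting only on class I HDACs makes SCORE and SCORE I agree
on the planted set, which the suite asserts.

The generator emulates the linear dependency structure the analysis
assumes; it does not emulate microarray probe effects, platform noise,
batch structure, or the infiltration of patient samples by
non-cancerous cells. Passing recovery tests therefore demonstrates
correctness of the estimator and scoring pipeline under the model's own
assumptions, not robustness to those real-data confounders.

`simulate_combination` builds single-agent inhibitions from 4PL curves
(default ec50 2.0, hill 1, doses 0–2), sets combination inhibition to
the Bliss expectation plus a planted excess (clamped to [0, 1]; the
truth record stores the realised post-clamp mean), and adds Gaussian
viability noise. The default dose range keeps expected + 0.15 excess
inside [0, 1] so noiseless planted scores are exact. All randomness
flows from one seed through spawned child streams, so the HDAC block,
planted noise and null block are independently reproducible.

## Numerical and design choices

- Gene symbols match case-insensitively; duplicate rows collapse by
  mean; rows with any missing value are dropped (the elastic net needs
  a complete design) and counted in a load report.
- Expression is assumed log2-scale; `log2(x+1)` is available as an
  explicit flag for raw-scale matrices. No re-normalisation is applied
  before regression (a no-op by default, since the motivating cohorts
  ship pre-normalised).
- The empirical-covariance check on the generator runs at n = 10,000,
  where off-diagonal entries (0.3) have sampling sd ≈ 0.01; the test
  uses a 0.05 absolute band on the covariance scale with a fixed seed.
- CLI outputs contain the seed and no timestamps, so identical
  configurations are byte-identical on repeat.
- The heavy recovery study (50 seeds × n=500 × 10-fold CV over a
  15-pair grid, ~1.5 s per cohort) runs in about a minute on one CPU;
  permutation nulls reuse the selected penalty pair rather than
  re-running CV on permuted data.

## Known limitations

- The scores quantify expression association only; no causal or
  chromatin-mechanism claim follows from a high SCORE, and class IIb/IV
  HDACs beyond HDAC1–8 are excluded.
- Per-dataset penalty selection averages the CV surface over RTKs with
  equal weight; strongly heteroscedastic responses would argue for
  `gene` mode.
- The Bliss score is unweighted over the dose grid, so grid design
  (dose placement) influences the summary exactly as it does in common
  practice.
- 4PL fits on shallow or truncated curves can hit the ec50 bounds; the
  convergence flag and the interpolated IC50 should be consulted before
  trusting extrapolated values.
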