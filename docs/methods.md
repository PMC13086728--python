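# Methods

## Design construction and coding

A factor is specified by its natural low/high levels; the coded value is
`(natural − center)/half_range`, an exact affine bijection, so low/center/high
map to −1/0/+1. The Box–Behnken construction iterates over factor pairs in
declaration order (AB, AC, BC for three factors), placing the four (±1, ±1)
combinations with all remaining factors at 0, then appends `n_center`
replicated center runs (default 3, the replication used by the bundled
study). For k > 3 the same all-pairs rule is used (24 edge runs for k = 4,
40 for k = 5), the standard incomplete-block BBD. Run order is the
deterministic construction order; `randomize=True` with a seed shuffles rows
without changing the design. `validate_design` reports center-point count,
column balance (each main-effect column sums to 0), pairwise orthogonality
and out-of-range coded values; it never mutates its input.

Because the design is balanced and orthogonal, every main-effect
least-squares coefficient equals the contrast Σ(xᵢ·y)/8 over the eight runs
where that factor is at ±1, and the intercept of a main-effects model is the
response grand mean. Both identities are asserted in the tests as an
independent check on the regression path.

## Response-surface fitting and diagnostics

Fits are ordinary least squares (statsmodels `OLS`) on the coded model
matrix at one of three orders — linear (p = 4 terms for 3 factors), 2FI
(p = 7), quadratic (p = 10) — with rank checked up front; a rank-deficient
matrix raises an error naming the collinear terms. Term p-values are the
OLS partial t-tests, which on a balanced BBD coincide with sequential tests
for the main effects.

Diagnostics follow the conventions of commercial DoE software so that
numbers are comparable with published QbD studies:

* R² and adjusted R² use the corrected (mean-centred) total sum of squares.
* PRESS is computed from the leverage identity Σ(eᵢ/(1−hᵢᵢ))², which equals
  explicit leave-one-out refitting (asserted against a brute-force LOO loop);
  predicted R² = 1 − PRESS/SST and may legitimately be negative. A leverage
  of 1 (exact-fit point) makes PRESS undefined and raises.
* Adequate precision is the signal-to-noise ratio
  (max ŷ − min ŷ)/√(p·MSE/n); values above 4 are conventionally adequate.

Order selection (`select_model`) walks the ladder linear → 2FI → quadratic,
testing each added block of terms with a partial F-test (statsmodels
`compare_f_test`) at α = 0.05 by default; the highest rung with a
significant block wins and ties break toward the simpler model. Rungs
without residual degrees of freedom are skipped with a logged warning.
Per-run standard deviations of triplicate measurements are carried as
metadata only — the study reports per-run means and no weighting scheme, so
fits are unweighted.

The bundled study's 24-h permeation response is fitted as a main-effects
model. Its published equation's C coefficient (−72.28) is inconsistent with
the orthogonal-contrast estimate from the published run table (−75.28), and
the published particle-size intercept (33 920) is a scale typo for the grand
mean 339.20; the package reports the least-squares values and neither typo
is asserted anywhere.

## Desirability optimization

Per-response desirability is the Derringer–Suich ramp: for "maximize",
d = clip((y−L)/(U−L))^w; for "minimize" the mirrored ramp; "target" is the
two-sided tent; "in_range" an indicator. L and U default to the observed
response minimum/maximum in the design table — the convention of DoE
software when the analyst states only a direction — and predictions beyond
the favourable anchor saturate at d = 1. The composite is the
importance-weighted geometric mean D = (Π dᵢ^rᵢ)^(1/Σrᵢ), zero whenever any
dᵢ = 0; weights and importances default to 1.

The search maximizes D over the coded cube [−1, 1]³ from a fixed 5×5×5
lattice of starts ({−1, −0.5, 0, 0.5, 1} per axis), each refined with
bounded Nelder–Mead (xatol 1e−8, fatol 1e−10, max 2000 iterations). There
are no stochastic restarts, so identical inputs give bit-identical results.
A run where every start yields D = 0 returns the best point with a warning
rather than failing. On the bundled study this reproduces the published
optimum — 25 mg PLGA, ≈1.85 % w/v PVA, 0.5 ml internal aqueous phase,
D ≈ 0.998 — and the optimizer is additionally checked against a dense-grid
oracle on synthetic problems.

Percent prediction error for validating a fabricated optimum is the signed
100·(actual − predicted)/actual.

## Release kinetics and entrapment

Entrapment efficiency is 100·(total − free)/total from the indirect
(free-drug) assay. Cumulative-release profiles (% of dose vs hours) are fit
by linear regression on each model's linearizing axis: Q vs t (zero order,
k₀ in %/h), ln(100−Q) vs t (first order in percent-remaining form, k₁ in
1/h), Q vs √t (Higuchi, k_H in %/√h). The winning model is the largest R²
on its own transformed axis — the criterion the field reports — with the
caveat that this compares differently transformed residuals, not a
like-for-like information criterion. A t = 0 point with zero release is
excluded from the log transform; any point at or above 100 % release skips
the first-order fit with a warning; non-monotone profiles are flagged, not
silently repaired. When raw receptor concentrations are supplied instead of
percent profiles, the standard additive withdrawal correction
C′ₙ = Cₙ + (V_s/V_r)·Σ_{i<n} Cᵢ is applied first.

## Permeation analytics

Cumulative amount permeated per unit area at step n is
(V_r·Cₙ + V_s·Σ_{i<n} Cᵢ)/A, the sampled-and-replaced mass balance. The
steady-state window defaults to all points from the first time the local
3-point regression slope reaches 80 % of the terminal 3-point slope — a rule
chosen because published Franz-cell analyses rarely state their window — and
can be overridden explicitly. Jss is the window's regression slope, lag time
the x-intercept converted to minutes, Kp = Jss/C_donor (cm/h with C_donor in
µg/ml), EI = Kp/Kp_control. The donor concentration is study geometry the
bundled dataset does not fix; the default of 1 mg/ml is a documented
sentinel consistent with the dataset's printed Jss/Kp pairs, and EI is
independent of the choice since it is a ratio at shared C_donor.

## Synthetic studies

The generator emulates the data-generating processes the analyses assume: a
known quadratic surface plus i.i.d. Gaussian noise on a BBD (the study's
triplicate means are reported with roughly constant SD per response, so the
default emulation uses constant σ; σ = 3 in the Monte-Carlo tests is of the
order of the study's response SDs), exact kinetic curves plus noise clipped
to [0, 100], and flat-then-linear permeation curves. Simulated cumulative
series are monotonized by running maximum — a simulator artifact that is
never applied to measured data. What passing recovery tests show is that
the estimators are exact at zero noise and unbiased at realistic noise on
the design geometry used; they do not certify behaviour under correlated
errors, heteroscedasticity across runs, or model misspecification, none of
which the generator emulates.

Problem sizes throughout the tests and the acceptance script are the study's
own: 15-run designs, 7–9-point profiles, 200 Monte-Carlo replicates; the
whole suite runs in well under a minute.

## Numerical choices and edge cases

* Coded values are stored at full precision; natural values are derived
  views for reporting.
* A constant response fits with intercept = the constant and zero
  coefficients; R² is reported as 1 with undefined (NaN) adjusted R², and
  adequate precision raises on zero MSE.
* Orthogonality/balance checks use an absolute tolerance of 1e−9.
* Optimizer ties between starts break toward the earlier start in the fixed
  lattice order.
* CSV dialect: comma-separated, '.' decimal, UTF-8, mandatory header;
  `<response>_sd` columns round-trip as metadata. Configuration is TOML
  with unknown keys rejected at load.

## Known limitations

* Only the ramp (linear) desirability is implemented; no Pareto-front
  enumeration or uncertainty propagation onto D.
* No lack-of-fit test against pure error, Box–Cox transformation, or
  stepwise term pruning.
* Release models are limited to zero-order/first-order/Higuchi (no
  Korsmeyer–Peppas or Weibull), and permeation analysis does not estimate
  diffusion coefficients from lag time.
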