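# Methods

## Design construction and factor coding

A rotatable central composite design for k factors holds 2ᵏ factorial
points at coded ±1, 2k axial points at ±α with α⁴ = 2ᵏ, and n_center
replicated center runs. α is stored at full precision (1.68179… for
k = 3); "1.68" is a display convention. For the case-study factors the
coded→actual map uses `step = level(+1) − level(0)` from the published
level table: EtOH (center 50 %, step 29.76), time (35 min, 17.86),
solid-to-liquid ratio 4.4 %/2.14 for leaves and 11 %/5.35 for branches.
Two cells of that table are internally inconsistent with its own
symmetric coding: the branches −1 level is printed 5.56 where
11 − 5.35 = 5.65 (a digit transposition, confirmed by the +1 level
16.35 = 11 + 5.35), and the EtOH −α level is printed 0 which matches the
map only at the printed coded value 1.68, not the full-precision α
(which gives −0.05). The unrounded transform is authoritative
internally; extreme coded inputs that map to negative physical
quantities are allowed but warned about.

Run order is randomized only when an explicit seed is supplied, and the
seed is recorded in the design, so a design file is always reproducible.

## Model fitting and term selection

The full second-order polynomial (1 + k + k + k(k−1)/2 terms) is fit by
ordinary least squares; standard errors come from σ̂²(XᵀX)⁻¹ with
σ̂² = RSS/(n − p), t = β̂/SE, and two-sided p-values from the central t
distribution on the residual degrees of freedom. Selection is a single
pass: every term with full-model p ≤ 0.1 is retained (ties at the
threshold kept), the intercept always survives, and the retained set is
refit once. No hierarchy is enforced — the case study's thin-branch TPC
model keeps X₂X₃ without X₃, which rules out hierarchy-preserving
stepwise procedures. Screening df is that of the full model, the
effect-estimate convention of classical RSM software. With zero residual
variance (noiseless synthetic data) t statistics are degenerate; nonzero
coefficients get p = 0, zero coefficients p = 1, with a warning.

A rank-deficient model matrix raises an error naming the collinear
columns rather than silently pseudo-inverting.

## ANOVA and verdicts

Sums of squares are taken around the response mean: SS_total =
SS_regression + SS_residual, and SS_residual = SS_lof + SS_pure_error,
where pure error is the within-group sum of squares over runs with
identical coded coordinates (the center replicates in a standard CCRD;
the grouping generalizes to any replicated design). F critical values
use the F quantile (numeric inversion of the regularized incomplete
beta, via scipy), at the working level p ≤ 0.1 throughout —
configurable, but 90% is the study's convention. Verdicts: *significant*
requires strictly F_reg > F_tab; *predictive* requires strictly
F_lof < F_tab; a zero pure-error mean square yields "predictivity
undeterminable" instead of a division by zero, and an intercept-only
model is "not significant" by construction.

R² is reported as SS_reg/SS_total and adjusted R² as
1 − (SS_res/df_res)/(SS_tot/df_tot). In the published ANOVA tables the
rows labelled "Adjusted R²" numerically equal SS_reg/SS_total while the
rows labelled "R²" have no evident derivation; the labels are treated as
transposed and only the ratio is validated. Similarly, the thin-branch
TPC pure-error mean square is printed 105.40 where SS/df = 150.405; the
printed lack-of-fit F (5.46) matches 150.405, so the MS cell is treated
as a typo and mean squares are always recomputed from SS/df. One
consequence: the leaves lack-of-fit F from exact SS/df is 8.9148, while
the published 8.92 is the ratio of the *rounded* mean squares; tests
compare to within one unit of the last printed digit.

## Desirability optimization

The study names Harrington's methodology but prints only the acceptance
bands, not the transform. The package adopts the Derringer–Suich
one-sided linear ramp — d = ((y − low)/(high − low))^s clipped to [0, 1]
for maximization, mirrored for minimization — with the observed response
range as default anchors and exponent 1, matching common RSM-software
practice. Consequence: the published global D values (0.9199, 0.957) are
not reproducible without the unprinted anchors; only their band
classification ("quite acceptable") is checked. Global D is the
geometric mean, so any zero component vetoes a candidate point.

The optimum is found by a dense row-major grid scan of the closed cube
[−α, α]ᵏ (default step 0.01 coded units) followed by coordinate-wise
refinement with step halving to 1e-4. A grid-then-refine search was
chosen over derivative methods because reduced quadratics can be
indefinite and the argmax frequently sits on the cube boundary (true of
the published leaves surface in X₂). Ties resolve to the
lexicographically smallest coded point (first occurrence in the
row-major scan). Responses whose ANOVA verdict is not
significant-and-predictive are excluded from the aggregate by the
pipeline, mirroring the study's validation, which dropped leaves TPC and
thin-branch DPPH. Predictions are not clipped to physical ranges;
a DPPH prediction outside [0, 100] raises a warning.

Two published optima are mutually inconsistent with the published coding
(leaves: 64.88 % EtOH/6.23 % m/v in one place, 65.4 %/7.6 % in another;
branches likewise), and evaluating the printed thin-branch model at its
reported optimum gives 293.1, not the printed 291.30 (coefficient
rounding). These discrepancies are documented, not reconciled; the
package validates against the coded point (0.5, −0.5, 1.5) and the
printed prediction 63.48 %, which are self-consistent.

## Assay arithmetic

DPPH inhibition uses the universal (A_c − A_s)/A_c × 100 form. The TPC
unit chain is owned by one operation: the calibration line returns the
gallic-acid-equivalent concentration in mg/L in the cuvette;
multiplying by the dilution factor and dividing by the extract-solution
concentration in mg/mL (≡ g/L) lands in mg GAE/g, so the factor-of-1000
conversion cancels exactly and is unit-tested by inverse round-trip.
The selectivity index is IC₅₀(RAW 264.7)/IC₅₀(cancer line), verified
against all nine published cells. Relative validation error is
|predicted − observed|/|predicted| × 100, and the study's "MAE (%)" is
read as the mean of per-replicate relative errors.

## Synthetic experiments

The generator draws yᵢ = surface(codedᵢ) + εᵢ with ε ~ N(0, σ²) i.i.d.
on the response scale. Defaults are the study conditions: the published
leaves surface as truth, the 17-run CCRD (8/6/3), and σ = 1.79 — the
square root of the published leaves pure-error mean square (3.191),
the only variance anchor available. Gaussian i.i.d. noise is an
idealization: real assay responses are heteroscedastic across the
design region, bounded (DPPH ≤ 100 %), and batch-correlated, so passing
recovery tests demonstrate correctness of the statistical machinery,
not that real extractions behave this well. Optional floor/ceiling
clamping emulates the bounded scale but is off by default to keep
recovery studies unbiased. One pseudo-random stream per experiment is
split by run index (seed-sequence spawn keys), so extending a design
never perturbs earlier draws.

The recovery harness repeats generate → fit → screen → ANOVA over
seeded replicates and reports coefficient bias/RMSE, per-term selection
frequency, confidence-interval coverage and verdict fractions. At the
study's noise level all eight true non-intercept terms of the leaves
surface survive the screen in ≳ 90 % of replicates, and under a null
(intercept-only) truth each term's selection frequency is the nominal
10 %. Note that the *post-selection* ANOVA verdict is optimistically
biased under the null (a reduced model assembled from the luckiest
terms is often "significant"); the package reports the verdict as the
study's procedure defines it and leaves post-selection inference out of
scope.

## Problem sizes and numerical choices

Simulation-based checks use 500 replicates for power/RMSE/coverage
summaries and 2000 for type-I calibration — sizes at which the binomial
standard error of a 0.10 frequency (≤ 0.007) is well inside the ±0.03
tolerance asserted. Optimizer tests use coarser grids (0.05–0.1) with a
10× finer brute-force oracle; the default step remains 0.01. Exact
identities (SS conservation, residual orthogonality, noiseless
recovery, round-trips) are asserted at 1e-8 absolute or relative, and
the coded↔actual round-trip at 1e-12.

## Known limitations

- Single-pass selection with full-model df is one of several defensible
  screening conventions; the choice is forced here by the published
  reduced models, not derived from first principles.
- The desirability anchors default to the observed response range, so D
  values depend on the data realization, not only on the surface.
- Pure error is estimated from center replicates only in the standard
  design; with no replicated runs the ANOVA refuses rather than guesses.
- IC₅₀ estimation from raw dose-response curves is out of scope; only
  the ratio arithmetic on given IC₅₀ values is implemented.
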