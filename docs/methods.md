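# Methods

This note records the statistical conventions, default parameters and design
choices behind `mixdes`, and what its tests do and do not establish.

## Design space and coding

The design space is the polytope {L ≤ x ≤ U, Σx = total}. All fitting,
design selection and coefficient reporting use L-pseudo-component coding
x′ = (x − L)/(total − ΣL), which maps the lower-bounded region onto the unit
simplex. This choice is forced by the embedded study equations: evaluated at
the optimized composition they reproduce the published predicted particle
sizes (97.2 / 98.4 nm) only in pseudo coding (denominator 5.5 wt% for the
embedded region), not in raw proportions. A converter to real-proportion
coding exists for inspection; predictions are invariant between the codings
because they are affine re-parameterizations of the same column space.

Candidate points for design selection are the 3-level grid {L, (L+U)/2, U}
over the freely varying components, with the widest-range ("filler")
component computed by difference and infeasible points discarded. On the
embedded region this yields 81 candidates containing every distinct run of
the published design; on an unconstrained simplex it reduces to the classic
vertex/edge-midpoint/centroid set. The region centroid is the mean of the
bound-combination vertices (which is the mid-range point on a full box and
(1/q, …, 1/q) on a simplex). Regions whose polytope has vertices outside the
bound-combination family (possible with several simultaneously active
implied constraints) are outside this constructor's scope.

## D-optimal selection

Point exchange: from a seeded random full-rank subset, repeatedly apply the
single swap (design point ↔ unused candidate) that most increases
det(XᵀX), until no swap improves it; 10 restarts by default, ties broken
toward the lower candidate index, determinants recomputed from scratch at
each accepted swap (designs here are tiny; no rank-1 updating is needed).
Replicate slots — four by default, mirroring the published design's centroid
replicates — are pinned to the region centroid and included in the objective
matrix. Exact reproduction of any particular software's 24 chosen rows is
not a goal; the contract, enforced by test, is D-efficiency
det(XᵀX/n)^(1/p) at least equal to the published design's, and agreement
with exhaustive search on instances small enough to enumerate.

## Fitting and ANOVA

Scheffé polynomials are fit by no-intercept least squares using an
orthogonal-decomposition solver; the explicit normal-equation solution is
kept as a test oracle only. The total sum of squares is mean-corrected:
under the mixture constraint the linear columns sum to one, so the constant
lies in the model space and the mean-response null model is the correct R²
baseline (uncorrected totals would push all R² values toward 1 and cannot
reproduce the published magnitudes).

ANOVA rows: overall model (df p − 1, F against the residual MS),
one row per interaction term using the partial (single-term-deletion) extra
SS — single-component terms get no individual test, as they are not
separately estimable under the mixture constraint — and the residual split
into lack of fit and pure error whenever the design carries replicate groups
(compositions identical to 1e-9). No multiple-testing correction is applied
across term rows. Adequate precision is
(max ŷ − min ŷ)/√(p·MS_res/n); a residual MS at floating-point zero
returns an infinity sentinel with a warning.

Model selection fits linear, quadratic and special cubic (when n > p) and
promotes to a higher order only if the added term block passes its
sequential F-test at α = 0.05, lack of fit stays non-significant, and
adjusted R² improves. The overall F of a richer model inherits the
lower-order signal, so the block test is what justifies an upgrade; with the
overall-F rule instead, simulation shows a linear truth being "upgraded"
about half the time, against the ~5% nominal rate the sequential rule
achieves.

## Optimization and validation

Desirability: responses map linearly onto [0, 1] between their minimum and
maximum over a dense region grid (21 levels per free component by default);
component directives map linearly over the component's bounds, with
triangular desirability for target directives. The weighted geometric mean
is maximized by grid seeding plus a deterministic shrinking-step pattern
search on the simplex slice, so the result never falls below the best grid
point (asserted in tests).

The study this package embeds states its optimization criterion only
verbally ("smallest response at minimal component amounts"), which does not
determine a unique optimum — notably, the reported optimum has oil at its
upper bound although oil increases particle size. The packaged goal file
(`paper_goal.yaml`) therefore encodes the formulators' choices explicitly:
all four responses minimized, oil maximized at triple weight (drug payload:
more oil dissolves more of the lipophilic drug), lecithin and glycerol held
at their selected 2.5 wt% levels by target directives. Under this
configuration the desirability optimum is exactly the reported composition;
under other defensible configurations (e.g. equal-weight response
minimization alone) it is not. Reproducing the reported optimum is thus a
fixture test of the shipped configuration, not a claim that the verbal
criterion implies it.

Validation reports RSE% = 100·(actual − predicted)/predicted per
formulation and response, displayed by magnitude at 2 dp; records above a
configurable 5% bound are flagged. RSE is not antisymmetric — swapping
actual and predicted changes the denominator, so magnitudes differ — which
the tests document numerically.

## Aerosol metrics

ED = device-part deposits plus all stage and filter deposits; the nebulizer
medication chamber is tracked separately and excluded (drug never emitted).
PD = 100·ED/TD. PI = 100·(stage mass)/TD; whether the backup filter counts
as a stage is genuinely ambiguous in practice, so it is included by default
and excludable by flag. FPF = 100·(stage-4-through-filter mass)/ED, with the
start stage configurable by label.

MMAD is the 50th percentile of the cumulative-undersize curve built from the
stage cutoffs, interpolated linearly in log10(diameter); GSD is
√(d(84.13)/d(15.87)) by the same interpolation. Probit-scale interpolation
is available behind a flag and agrees with log-linear near the median on
lognormal clouds. Degenerate runs (all mass in one stage window) report the
geometric mid-window diameter and GSD 1 with a warning. The default cutoff
table fixes the four windows the study prints (4.70/3.3/2.10/1.10/0.65 µm
for stages 3–6) and fills the unprinted stages (0, 1, 7) with the classic
Andersen values (9.0, 5.8, 0.43 µm); it is configuration, meant to be
replaced when a flow-calibrated table is available.

## Synthetic data

Response simulation adds i.i.d. Gaussian noise to a known Scheffé surface —
the homoscedastic error model the ANOVA assumes — with default SD 0.7 nm,
the residual scale of the embedded particle-size fit (√0.47). No run-order,
block or heteroscedastic effects are simulated, so passing recovery tests
says nothing about drift or variance structure in real instruments.
Impactor simulation draws 10⁶ equal mass quanta by default from a lognormal
aerodynamic distribution (median 3.2 µm, GSD 1.7, the embedded study's
scale), bins them by the cutoff table, diverts 30% of the loaded dose
upstream of the stages (1% of it onto the device parts, the rest to chamber
retention), making percent dispersed ≈ 71% by construction. Binning plus
log-linear interpolation recovers the median within ±0.15 µm and the GSD
within ±0.1 at that resolution — the recovery bias of the interpolation
rule across the coarse stage windows, not sampling noise, dominates the GSD
error. All generators are bit-reproducible for a fixed seed (numpy PCG64).

## Known, documented discrepancies

The embedded response tables are printed at two decimals, which is enough to
reproduce R² values and most mean squares but not every published statistic
exactly. Refitting the printed tables gives: model F 84.4 vs published 81.30
for the docetaxel particle-size fit (the printed residual MS 0.47 refits to
0.45), CCM adequate precision 68.0 vs published 64.87, and a published
pairwise coefficient (−191.85) that refits to −194.6. The curcumin
aerosol-size column is irreproducible outright (refit R² 0.05 vs published
0.7610), suggesting a transcription problem in that printed column; the
package keeps the column as-is and the model-selection fallback ("linear
with warning") handles it. The corresponding acceptance tests assert the
published values at their stated tolerances and are expected to fail on
these quantities; they document the irreproducibility rather than hiding it.

## Problem sizes

All refits are 24 × ≤15 least-squares problems and run in milliseconds. The
simulation-backed tests use 200 model-selection repetitions, 500 null-ANOVA
repetitions and one 10⁶-quantum impactor cloud, sized so the full suite
completes in well under a minute while keeping Monte-Carlo error far inside
the asserted bands.
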