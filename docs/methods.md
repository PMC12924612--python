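# Methods

## Problem and model

`rocpower` plans paired diagnostic-accuracy studies: two tests are read on
the same N₊ cases and N₋ = R·N₊ controls, each test is summarized by its
ROC area θᵢ, and the study asks whether θ₂ differs from θ₁.  Scores are
modelled as binormal — controls N(μ₋, σ₋²), cases N(μ₊, σ₊²) — so each ROC
curve is described by the location A = (μ₊−μ₋)/σ₊ and scale ratio
B = σ₋/σ₊, and the (partial) area is ∫ Φ(A+Bv)φ(v)dv between the z-scale
FPR thresholds.  Designs are stated in AUC terms and converted through the
full-range closed form A = √(1+B²)·Φ⁻¹(θ); the package never fits the
binormal model to data (no rating-MLE), it only evaluates design-stage
formulas.

The test statistic is Z = Δ̂/√(V₀(Δ̂)/N₊) with Δ̂ = θ̂₂ − θ̂₁.  Sample size
follows the standard two-variance normal formula (null variance under H₀,
alternative variance under H₁), solved in closed form and rounded up per
group.  Power at a given N₊ inverts the same relation, so
`power_at_n(required_n(d).n_pos) ≥ target > power_at_n(n−1)` holds by
construction and is verified across the whole scenario grid.

## Variance engines

**Rating (discrete) data.**  The variance of a single binormal AUC estimate
and the covariance of two paired estimates are evaluated from the constants
f, g, E₁–E₄ of the binormal model (module `binormal`), with within-group
inter-test correlations r₊ (cases) and r₋ (controls) entering the
covariance.  Two conventions deserve note:

* *Null-variance anchor.*  The null variance is evaluated with **both**
  tests at the first test's parameters: V₀ = 2[V(θ̂₁) − C(θ̂₁,θ̂₁)].  The
  source formulation is degenerate as printed; anchoring at AUC₁ is the
  reading that reproduces the published scenario tables exactly, and the
  package adopts it for both engines.  Anchoring at the mean of the two
  areas does not reproduce them.
* *Thresholds.*  The variance constants use the location/scale-adjusted
  z-thresholds c = (Φ⁻¹(FPR) + AB/(1+B²))/√(1+B²); the AUC integral uses
  the plain c = Φ⁻¹(FPR).  Both conventions coincide in effect on the full
  FPR range (E₃ = 1, E₄ = 0 exactly), which is the only regime pinned by
  published values; partial-range designs are computable but carry no
  external validation.

**Continuous data.**  Single-AUC variances use the Wilcoxon-statistic
closed form (the Q₁/Q₂ decomposition).  The covariance is C = r·√(V₁V₂) —
*not* 2r√(V₁V₂) as sometimes printed, which violates nonnegativity of
V(Δ̂) for r > ~0.5 and reproduces no published number.  The continuous
engine is restricted to the full FPR range.

## The area-correlation table

The user knows the correlation ρ between the two tests' *scores*; the
covariance formula needs the correlation r between the two *area
estimates*.  The packaged lookup table
(`rocpower/data/area_correlation_synthetic.csv`) maps (ρ, mean area) → r
with bilinear interpolation; support is ρ ∈ [0, 0.9], area ∈ [0.70, 0.90],
and lookups outside it raise rather than extrapolate.

The table is a **synthetic reconstruction**, not a digitization of the
historical reference table.  Its anchor rows at ρ = 0.3, 0.5, 0.8 were
calibrated by inverting the sample-size formula against the published
scenario tables for a 0.80 baseline area (r ≈ 0.259, 0.448, 0.760 at mean
area 0.81, declining gently with area); with these anchors the continuous
engine reproduces all twelve published per-group sizes exactly (2807, 2092,
909, 693, 517, 225, 304, 100, 169, 56, 107, 36).  The feasible r windows
pinned by those sizes are as narrow as ±0.0002, which rules out every
2-decimal published table under any interpolation rule, as well as the
exact asymptotic binormal correlation (off by 0.002–0.006); the calibrated
reconstruction is therefore the honest option, and it is labelled as such
in the file and its docstrings.  Rows at other correlations are monotone
(PCHIP) interpolants between r = 0 at ρ = 0 and r = 1 at ρ = 1; they are
smooth and order-preserving but carry no external validation.

## Attrition

With dropout rate DR, each group's enrollment is DISS = ⌈n/(1−DR)⌉ and the
expected dropouts are ED = DISS − n, applied per group after the
sample-size solve.  Dropouts are assumed uninformative (missing at random),
matching the design-stage convention of inflating enrollment rather than
modelling the missingness.

## Monte-Carlo validator and synthetic scores

`simulate` draws paired scores from the model the formulas assume: controls
from a bivariate normal with zero means, SDs (B₁, B₂) and correlation ρ₋;
cases from a bivariate normal with means (A₁, A₂), unit SDs and correlation
ρ₊.  Marginally each test's population AUC is exactly the design AUC.  Per
replication both Mann–Whitney AUCs (midranks, ties counted ½) are computed
and H₀ rejected when |Δ̂| exceeds z₁₋α/₂·√(V₀/N₊) with the *analytic*
plug-in null variance — the statistic whose power the analytic formulas
describe.  The rejection proportion over replications estimates the actual
power, reported with its binomial standard error.  Reproducibility: one
root PCG64 seed spawns an independent substream per replication.

Default replication count is 1000 (the validation tests use 1000; binomial
SE ≈ 0.013 at power 0.80), a deliberate scale-down from exhaustive
validation runs; the acceptance checks allow 2.5 binomial SEs.

What the generator does *not* emulate: non-normal (skewed, heavy-tailed)
scores, verification bias, clustered readings, or informative dropout.
Passing simulation checks therefore validate the internal consistency of
the analytic formulas under the binormal model, not their robustness to
real-data violations of it.

Rating-data mode discretizes the latent scores into `rating_levels` ordinal
categories (default 5) at equiprobable quantiles of each test's control
distribution.  Discretization introduces ties and shrinks the effective
AUC (≈0.774 observed for a latent 0.80 at five levels), so simulated power
for rating designs sits below the latent-scale target; the rating-data
variance formulas describe a parametric rating estimator, not the
tie-adjusted Mann–Whitney statistic, and the package treats the rating-mode
simulation as qualitative. Consistently, the n-scaled Monte-Carlo variance
of the Mann–Whitney AUC converges to the Wilcoxon-form variance (0.098 at
θ = 0.80, R = 1), with the rating-data formula (0.120) sitting above it as
a conservative envelope; the test suite checks both facts.

## Numerical choices

* Quadrature for partial areas: adaptive Gauss–Kronrod (`scipy.integrate.quad`),
  absolute tolerance 1e−12; full-range areas use the closed form directly.
* Integer rounding: ceilings applied per group with a 1e−9 guard against
  float noise at exact boundaries (e.g. a real solve landing on 692.9999998).
* Degenerate inputs: equal AUCs raise an infeasible-design error from
  `required_n` (infinite n) but are legal in the simulator (type-I-error
  studies); boundary rates/areas (0 or 1) are rejected wherever a normal
  deviate of them would be infinite.
* Correlations are accepted separately for cases and controls in the rating
  engine; the continuous engine averages them, and the scenario grid ties
  them, matching the published study conditions (B₁ = B₂ = 1, equal
  allocation, α = 0.05 two-sided).

## Known limitations

* Partial-FPR-range sample sizes are computable for the rating engine but
  validated only at full range.
* The area-correlation table is calibrated at a 0.80 baseline area over
  ρ ∈ {0.3, 0.5, 0.8}; other regions of its support are smooth
  interpolation, not evidence.
* No multi-reader/multi-case designs, covariate adjustment, non-inferiority
  margins, or unequal-allocation optimization.
* Analytic power assumes the asymptotic normality of Δ̂; at very small
  groups (n ≲ 40) the simulator shows the usual small-sample erosion of
  the Z approximation.
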