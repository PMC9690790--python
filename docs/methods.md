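# Methods

## Model overview

The package evaluates a soil-stabilization treatment as a weighted
composite of 16 normalized indicators spanning the soil (fertility and
heavy-metal status), the crop (growth and heavy-metal accumulation) and the
amendment (cost, intrinsic heavy metal, stability). The composite score

S = Σ_i ω_i · X_i,  X_i ∈ [0, 1],

is computed once for the untreated soil and once per treatment; each S is
binned into five equidistant grades (I: (0.8, 1] … V: [0, 0.2]) and the
verdict is the grade-step change, before minus after, on the index scale
I = 1 … V = 5: more than one step of improvement is *excellent*, one step
*good*, no change *qualified*, one step of decline *poor*, more *very
poor*. A composite of exactly 0 falls outside the half-open grade-V bin as
written and is assigned grade V.

## Weights (AHP)

Weights come from expert pairwise comparisons. Each judgment matrix is a
positive reciprocal matrix; in strict mode (questionnaire ingestion) the
entries must be Saaty values {1/9 … 1/2, 1 … 9}, while synthetic perturbed
matrices are validated without that restriction. Priorities use the
sum-product method — column-normalize, row-sum, renormalize — which is
exact on consistent matrices and a one-step approximation to the principal
eigenvector otherwise; a dense eigen-decomposition serves as an independent
oracle in the test suite only. λ_max is estimated as (1/n) Σ (Aw)_i / w_i.

Consistency: CI = (λ_max − n)/(n − 1), CR = CI/RI with the standard RI
table for n = 1 … 9, acceptance at CR < 0.1. For n ≤ 2 a reciprocal matrix
is always consistent and RI = 0 would divide by zero, so CR is defined as 0
and the test passes. For n > 9 no RI value is shipped and the order is a
hard error rather than a silent extrapolation.

Panel aggregation: matrices failing CR < 0.1 are excluded (and reported);
the survivors' priority *vectors* are averaged arithmetically, optionally
with per-expert weights, and renormalized. Vector aggregation is the
default because it preserves the sum-to-1 contract trivially; an
entrywise geometric-mean aggregation of the matrices themselves — the
standard alternative that preserves reciprocity — is available by flag.

Hierarchy composition multiplies local weights down each root path; sibling
weights must sum to 1 (tolerance 1e−6). The packaged hierarchy carries the
published criterion and sub-criterion weights (soil 0.544 with fertility
0.295 / heavy metal 0.705; crop 0.316 with growth 0.265 / accumulation
0.735; amendment 0.140). Indicator-level local weights are back-computed as
each printed comprehensive weight divided by its sibling-group sum, because
the source table prints only the comprehensive values at that level — and
those printed values sum to 1.003 through rounding. Both weight sets are
available: `printed` (verbatim, sum 1.003) and `renormalized`/`composed`
(sum exactly 1). Evaluation defaults to the printed set, which is what the
reference pot experiment used.

## Indicators and transforms

* Group I (national-standard): soil total heavy metal, edible-part heavy
  metal, amendment heavy metal. Each carries a hard compliance limit
  checked alongside scoring; a violation is surfaced as a flag and never
  folded into the score, and it does not veto the verdict.
* Group II (farmland classification): pH, SOM, CEC, available N/P/K,
  biomass, production, cost. Production and biomass are ratios to a
  *mandatory* local reference (average local production / crop weight);
  cost is cost over crop revenue. References are configuration inputs,
  never estimated from data.
* Group III (no external criterion): available heavy metal via the
  reduction rate α = 100·(X_b − X_a)/X_b, plant burdens via the
  bio-accumulation factor BAF = 100·[X]_crop/[X]_soil, amendment stability
  in years against a 3-year life-cycle criterion.

α may be negative when the available fraction rises after treatment; it is
returned with a warning and scores 0 downstream rather than raising.
Classification helpers partition their domains with upper-closed BAF
classes (very weak ≤ 1 % < weak ≤ 10 % < moderate ≤ 100 % < strong) and
lower-closed α grades (poor [0, 25), medium [25, 50), good [50, 75),
excellent [75, 100]).

## Scoring curves

All three curves are piecewise linear, continuous, and clamped to [0, 1]
for every real input:

* S type: 0 below L, (x − L)/(H − L) on [L, H], 1 above H;
* inverse S: the complement on shared thresholds;
* parabolic/midpoint (pH only): 0 outside [L1, H1], rising limb
  (x − L1)/(L − L1), plateau 1 on [L, H], falling limb (H1 − x)/(H1 − H).

Two deliberate corrections to the published threshold table are applied,
both required to reproduce the reference scores:

* the parabolic rising limb is (x − L1)/(L − L1); the printed x/L1 form
  exceeds 1 and is discontinuous at L1;
* the available heavy metal is scored on a *rising* ramp of α with
  H = 75 % (s-type), although the table lists it under the inverse-S block:
  every reference score increases with the reduction rate (0 → 0,
  24.9 % → 0.33, 47.4 % → 0.63), which only the rising ramp matches.

Blank lower thresholds default to L = 0. Values reported as "> x" (e.g. an
amendment stability of "> 3" years) are parsed as lying just above the
bound and score accordingly. Scores are computed at full precision;
two-decimal rounding is display-only.

## Composite score and missing data

Indicators that were not measured contribute nothing and the weights are
*not* renormalized over the measured subset — the convention of the
reference experiment, where the untreated pot has no amendment, production,
edible-part or total-metal rows and scores 0.164 out of the full weight
budget. A `renormalize_missing` option rescales the measured indicators'
weights to sum 1 for complete designs; it departs from that convention and
is marked as such.

## Fixture assumptions (back-computed, not published facts)

* BAF denominator: the 5.0 mg/kg Cd spike, not spike + 0.18 mg/kg
  background; the denominator is always taken from input
  (`soil_total_hm`), never computed.
* Biomass reference 1.27 g with the ratio capped at 1 (curve H = 1.0 on the
  ratio scale, equivalent to reference 1.5875 g with the printed H = 0.8).
  Both are flagged `assumption: true` in the registry.
* Heavy-metal thresholds shipped are cadmium values; other metals are
  configured per metal by the user via the registry's `by_metal` blocks.

With the printed weights, full-precision recomputation of the reference
experiment gives composites 0.1643 / 0.3739 / 0.4745 against the published
0.165 / 0.371 / 0.471 — the ±0.003 drift is two-decimal rounding of the
per-indicator scores propagating through Σ ω_i X_i, so composite
comparisons in the tests use a ±0.005 band while per-indicator scores are
checked to two decimals.

## Synthetic generators

Expert panels: judgment matrices b_ij = (w_i/w_j)·exp(ε_ij) around a
ground-truth w, with antisymmetric Gaussian ε of scale σ (default 0.1, a
mild disagreement under which nearly all order-3 matrices keep CR < 0.1),
optionally snapped to the nearest Saaty value in log space with the lower
triangle set to the exact reciprocal. The antisymmetric multiplicative
noise is the minimal model preserving reciprocity exactly. Default panel
size is 20 experts, the size of the questionnaire the packaged weights came
from. The eigen-oracle comparison in the acceptance tests uses σ = 0.2 —
calibrated once on consistent-up-to-noise draws, where the sum-product and
eigenvector weights agree within 0.02 per component over orders 3–7 — with
1000 matrices per run.

Studies: per-indicator fixed values or uniform ranges per treatment; the
control treatment supplies X_b for reduction-rate indicators and the spec's
soil total attaches to BAF indicators, so generated records satisfy the
measurement invariants by construction. All generators are pure functions
of (spec, seed); the spec tuned to the reference experiment reproduces the
packaged CSV byte for byte.

What the generators do *not* emulate: replicate-level measurement error
(the reference table's ± standard deviations are not resampled), temporal
dynamics of the available metal (sampling-day effects), correlations among
fertility indicators, or multi-metal contamination. Passing tests therefore
demonstrate the pipeline's arithmetic and contracts, not robustness of the
evaluation design to noisy field data.

## Numerical choices and limitations

* Tolerances: reciprocity 1e−9; sibling-weight sums 1e−6; weight-vector
  normalization 1e−9; grade boundaries are half-open exactly as specified,
  with a 1e−9 guard on the [0, 1] domain check.
* Indicators measured for several metals are scored per metal upstream;
  the shipped registry models a single metal at a time (the reference
  study is Cd-only). Combining multiple metals is out of scope.
* The evaluation is static: no modeling of the available metal's
  adsorption/desorption dynamics, no entropy-weight or CRITIC corrections
  to the subjective AHP weights, no microbial or enzymatic indicators, no
  life-cycle economics beyond the cost/revenue ratio.
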