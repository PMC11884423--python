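# Methods

This note documents the statistical model, the estimators and tests, the
numerical choices, and the design decisions behind `seamsel`, together
with what the simulation engine does and does not emulate.

## Design and notation

A two-stage seamless phase II/III trial has a control group (g = 0) and G
treatment groups (g = 1..G). Stage 1 observes the short-term binary
endpoint for N_g(1) subjects per group; the treatment with the highest
stage-1 short-term response rate is selected (ties go to the smallest
index — the lowest dose, for safety). Stage 2 enrolls N_g(2) further
subjects in the control and selected groups only. The final analysis
compares long-term responders Y_0 and Y_s pooled over both stages.
X_g(j), Y_g(j), Z_g(j) denote short-term, long-term and dual responder
counts in stage j; ξ_g, π_g, ρ_g the short-term probability, long-term
probability and per-subject endpoint correlation. The information
fraction τ sets N_g(1) = round(τ N_g).

An optional control-inclusive selection rule is implemented (the control
"winning" means an early stop for lack of benefit); estimation and
testing refuse stopped trials, since the final analysis is only defined
for continued ones. How ties between control and a treatment interact
with that rule is not settled externally; the package applies the same
smallest-index convention (control index 0 wins), which is flagged here
as a convention, not an established fact.

## Bivariate binomial endpoint model

Each subject contributes a Bernoulli pair: long-term response with
probability π, then short-term response with probability
(β + α)/(1 + α) for long-term responders and β/(1 + α) for
non-responders, with β = ξ + α(ξ − π). Aggregated over n subjects,
X | Y = y is the convolution Bin(y, (β+α)/(1+α)) + Bin(n−y, β/(1+α)),
and both margins are exactly binomial.

**Dependence parameter.** The moment identity of this construction gives

    ρ = r · α / (1 + α),   r = sqrt(π(1−π) / (ξ(1−ξ))),

so the package uses α = ρ / (r − ρ). This orientation is the one under
which the per-subject Pearson correlation of simulated data equals the
nominal ρ (verified by simulation at 10^6 pairs for several unequal-margin
settings); with ξ = π it reduces to α = ρ/(1−ρ).

**Admissible range.** Validity of the generating construction alone
requires β ∈ [0, 1] and both conditional probabilities in [0, 1]. The
package additionally requires the same conditions for the
reciprocal-ratio candidate α′ = ρ / (1/r − ρ). This stricter, symmetric
rule is adopted deliberately: it pins the admissible boundary for
(ξ, π) = (0.7, 0.5) between ρ = 0.5 (admissible) and ρ = 0.6
(inadmissible), matching the published admissible range of this model
family, which the generating-construction condition alone does not. With
equal margins the two candidates coincide and the whole range ρ ∈ [0, 1)
is admissible. `rho_max(xi, pi)` computes the boundary by bisection;
plug-in correlations are clamped to [0, rho_max − 1e−9] and plug-in
probabilities to [0.5/n, 1 − 0.5/n] before entering any pmf, so that
degenerate estimates (all-zero responders) never produce an undefined α.

**Sampling** is per-subject (vectorized over replicates), not
count-level, so the dual-responder count Z — needed by the Rao–Blackwell
estimator and the correlation likelihood — is exact by construction.

## Selection probabilities

Pr(Q = s | X_s(1) = k) is a product over competitors h of binomial CDF
terms Pr(rate_h < k/n_s) (strict for h < s, weak for h > s, honoring the
tie-break). All rate comparisons use exact integer cross-multiplication,
never floats, so exact ties are detected even with unequal stage-1 sizes
(the case-study design has 28 vs 27). For a competing group g,
Pr(Q = s | X_g(1) = k) sums the selected group's count out against the
remaining groups via suffix sums; for the control under the
treatment-only rule the count is uninformative and the unconditional
Pr(Q = s) is returned. E[π_s] = Σ_s π_s Pr(Q = s) is exact enumeration,
no simulation.

## Estimators

**MLE.** Pooled proportions X_g/N_g, Y_g/N_g for continued groups,
stage-1 proportions for unselected groups; ρ̂ is Pearson's correlation of
the per-subject pairs computed from pooled aggregate counts, with a
neutral fallback of 0 when a margin is degenerate. Pooling over both
stages is assumed (whether the original definition used stage-1-only
pairs is not stated externally; pooled uses all information).

**CMAE.** The conditional biases

    b_{ξ,g} = Σ_k k Pr(X_g(1)=k) Pr(Q=s | X_g(1)=k) / (N_g Pr(Q=s))
              + (N_g(2)/N_g) ξ_g − ξ_g

(stage-2 term dropped for unselected groups) and the analogous double sum
for b_{π,g} over the stage-1 joint law of (X_g(1), Y_g(1)) are evaluated
at the MLE plug-ins and subtracted; results are clipped to [0, 1] after
subtraction (bias subtraction can overshoot at boundary data). The
control's bias is exactly zero under the treatment-only rule; the
long-term bias vanishes when ρ = 0. Both closed forms are validated to
1e−12 against brute-force enumeration on a G=2, n1=n2=2 design.

**UMVCUE.** Stage-2 data are untouched by the interim analysis, so
X_g(2)/N_g(2) and Y_g(2)/N_g(2) are conditionally unbiased;
Rao–Blackwellizing them against the sufficient statistics yields ratio
formulas over the unobserved stage-1 split. For the long-term
probability the split of the four per-subject response cells between
stages is multivariate hypergeometric given the totals — parameter-free,
which is exactly why the statistic is sufficient — giving a triple sum
over (kx, ky, kz) with coefficient

    c = C(n1, ky) C(n2, Y−ky) C(ky, kz) C(n1−ky, kx−kz)
        · C(Y−ky, Z−kz) C(n2−Y+ky, X−kx−Z+kz),

out-of-range triples contributing zero through the C(a, b) = 0
convention. Conditional on the selection event and the other groups'
stage-1 counts, the selection weight for the selected group is a 0/1
indicator of the rule (all competitors are fixed by the conditioning),
not a probability. For the control the weights are constant and the
estimator collapses to the pooled MLE. Conditional unbiasedness is
verified to 1e−12 by full enumeration across a parameter grid. The
estimator needs stage-2 subjects (n2 ≥ 1) and dual-responder counts; it
is undefined for unselected groups (no stage-2 data exists), where the
stage-1 MLE is carried instead.

**Correlation by profile likelihood (CMAE/UMVCUE).** With the margin
estimates held fixed, ρ̂ maximizes the per-subject four-cell multinomial
log-likelihood of the aggregated counts (dual, short-only, long-only,
neither) over the admissible ρ interval: a 200-point grid pre-search
(the likelihood can be flat near boundaries) followed by bounded scalar
refinement to 1e−6. The cell likelihood is used rather than the
likelihood of the (X, Y) pair alone because a single pair of totals
leaves ρ essentially unidentified — the dual-responder count carries the
correlation information; with it, ρ is recovered to ±0.02 at n = 10^4 in
the parameter-recovery test.

## Exact and mid-p tests, confidence intervals

Conditional on Q = s and T = Y_0 + Y_s = t, the law of Y_s is the tilted
family

    Pr(Y_s = k) ∝ C(N_0, t−k) h_{π_s}(k) exp(k Δ_s),
    h_{π_s}(k) = Σ_r C(N_s(1), r) C(N_s(2), k−r) Pr(Q=s | Y_s(1)=r),

over k = max(0, t−N_0) .. min(t, N_s), with Pr(Q=s | Y_s(1)=r) obtained
by mixing the closed-form selection probabilities over the conditional
law of X_s(1) given Y_s(1) = r from the bivariate binomial model at
plug-in estimates (any of the three estimator families; the caller
chooses, giving the six method combinations). With constant weights
(G = 1, or ρ̂ = 0) h reduces to C(N_s, k) by the Vandermonde identity and
the Δ = 0 law is central hypergeometric, so the exact test collapses to
Fisher's one-sided exact test — verified against scipy's hypergeometric
tail.

The exact p-value is sup over Δ ≤ 0 of the upper tail Pr(Y_s ≥ y_s); the
mid-p value adds only half the atom at y_s. The family has monotone
likelihood ratio in Δ, so the supremum is ordinarily attained at Δ = 0;
rather than assuming this, the package evaluates the tail on the grid
Δ ∈ {−10, −9.5, …, 0} and refines any interior maximizer by bounded
scalar optimization (1e−6). All tilted-pmf arithmetic is in log space
(supports reach k ≈ 280 in the case study, where k·Δ would overflow).

Confidence limits invert the tails in the Clopper–Pearson manner: the
lower limit is inf{Δ : Pr(Y_s ≥ y_s | Δ) > α/2}, the upper
sup{Δ : Pr(Y_s ≤ y_s | Δ) > α/2}, found by bisection on [−30, 30] (wider
than any estimable effect at these sample sizes) to 1e−6, with ties
extending the interval (conservative). Observed values at the support
boundary give infinite limits; a degenerate support (t = 0 or
t = N_0 + N_s) gives (−∞, ∞). If the bracket shows no sign change —
tail monotonicity failed numerically — a 4001-point grid scan is used
instead and a warning logged; this path has not been observed to trigger
in practice.

## Simulation engine

`run_study` simulates R trials per setting (per-subject generation,
selection by the rule, stage 2 for control and selected group only),
applies the requested estimators, tests (level 0.025 one-sided) and 95%
two-sided intervals, and reports means and RMSE of the selected group's
estimates against the *realized* selected group's true values per
replicate, rejection percentages, and coverage of the realized true
Δ_s, each with Monte Carlo standard errors. Replicates with infinite
interval limits are included in the coverage denominator (an infinite
limit can still cover the truth). Results are bit-reproducible given the
seed; all randomness flows through one explicitly threaded numpy
generator.

Scenario families: (1) global null at a common baseline in
{0.1, 0.5, 0.7}; (2) null with different short/long baselines (ξ in
{0.3, 0.7}, π = 0.5), where the admissible correlation range restricts
ρ to {0.2, 0.4, 0.5}; (3) only the last treatment effective; (4) linear
dose effect 0.5 + gδ/G; (5) all treatments effective at 0.5 + δ; with
δ = 0.280 for N = 50 and 0.145 for N = 200.

**Study sizes.** The package's default study runs 10,000 replicates for
estimator operating characteristics and 5,000 for test/coverage
characteristics — the scale at which the acceptance checks and
`scripts/acceptance.py` operate, with ±3 Monte Carlo SE tolerances
(≈ ±0.002 on estimator means, ±0.7 percentage points on rejection rates,
±0.9 on coverage, ±1.6 on power). Larger R narrows these bands
proportionally to 1/√R.

**What the generator does and does not emulate.** Data are generated
exactly from the assumed bivariate binomial model with a common, known
ρ across groups and fixed per-group sample sizes. Passing tests
therefore demonstrate correctness of the estimators and tests *under the
model*: no model misspecification (e.g. different dependence structure
between endpoints), no dropout or missing stage-2 data, no sample-size
re-estimation, no selection of multiple treatments (estimation and
testing assume exactly one continued treatment), and no staggered
enrollment effects are represented. Real-data behavior under such
departures is outside what the simulation evidence shows.

## Known limitations

- Negative endpoint correlations are not supported (ρ ∈ [0, rho_max)).
- The CMAE inherits a small residual bias because its bias correction is
  evaluated at the (biased) MLE plug-in; this is visible in the study as
  a mean a few thousandths above the truth.
- The UMVCUE requires dual-responder counts; when a data set does not
  report them (as in the case study), only MLE and CMAE are available,
  with an externally assumed ρ.
- Multiplicity control is the weak-sense control built into the
  conditional tests; no additional adjustment is applied.
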