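# Methods

## Model and assumptions

The analytic model (`partnerchoice.model`) describes one focal
individual repeatedly choosing partners from an effectively infinite
population of unconditional cooperators and defectors, each purple or
teal. Interactions are instantaneous Stag hunt rounds with payoff
ordering R > T ≥ P > S; payoffs motivate the focal's preferences but do
not enter the association dynamics, which depend only on who cooperates.
Three bounded-rationality parameters govern choice:

| parameter | meaning | range | default in configs |
|---|---|---|---|
| ω (awareness) | probability of identifying and picking a cooperator when choosing a new partner | [0, 1] | 0.5 |
| s (stickiness) | probability of re-pairing after the partner cooperated | [0, 1] | 0.5 |
| b (color bias) | probability of picking purple absent awareness/stickiness | [0, 1] | 0.5 |
| ρ, τ | cooperator proportions among purple / teal agents | [0, 1] | 0.5, 0.5 |

The association distribution P(i) over the four partner types follows
the affine recursion `P(i+1) = (1 − sγ(i))ν + sγ(i)g(i)`; the cooperator
mass γ(i) has the geometric closed form with intercept
e = 1 − (1−ω)(1−γ₀) and rate f = s(1−ω)(1−γ₀). The closed form and the
recursion are implemented independently and cross-checked to 1e-10 over
random parameter tuples. Awareness acts only from iteration 1 onward:
P(0) is a pure color-bias draw, since awareness means inferring
cooperativeness from *observed* interactions and none have happened yet.

All type vectors use the fixed order
((purple, coop), (purple, defect), (teal, coop), (teal, defect)); the
cooperator-only vectors C and g are stored in that same order so that
ν = ωC + (1−ω)P(0) is a convex combination of like-indexed entries.

## Discrimination index

D(P) = (|P_pc−P_pd| + |P_tc−P_td|) − (|P_pc−P_tc| + |P_pd−P_td|), the
sum of absolute within-color (behavior) differences minus the sum of
absolute within-strategy (color) differences. D ∈ [−1, 1]; transposing
the roles of color and strategy negates it, relabeling colors leaves it
unchanged, and D = 0 exactly when no row or column of the 2×2 matrix
dominates the other element-wise.

Aggregate per-race D is computed from counts pooled across episodes;
confidence intervals are percentile bootstrap (default 5,000 resamples,
95% level) resampling whole episodes, implemented by multinomial
weighting. The percentile method and the 95% level are the simplest
defensible choices; no bias correction is applied.

Empirical estimators: awareness is the fraction of partnered races with
a cooperating partner (races without a partner drop out); stickiness is
the fraction of consecutive race pairs, both partnered, in which the
partner repeats. The stickiness estimator is unconditional — it does not
require that the earlier partner cooperated — matching how the
behavioral proportion is measured, whereas the parameter s in the model
conditions on a satisfactory interaction; the two coincide when partners
always cooperate, which is how the recovery test is constructed.

## Simulator

Finite mode: a community roster (default 12 agents — the smallest size
divisible by four, making the half/half color and strategy marginals
exact) is built from either a training bias c, mapped to
ρ = (1+c)/2, τ = (1−c)/2 (the unique linear map preserving the
marginals), or explicit (ρ, τ). Each episode samples 5 coplayers
without replacement; each of 8 races, the focal chooses first via the
stickiness → awareness → color-bias cascade and the remaining four
coplayers pair uniformly at random. The focal always cooperates: in a
Stag hunt the best response to a partner one chose for cooperativeness
is to cooperate, and the object of study is partner choice, not the
rowing policy.

Perceptual intervention: after every race each cooperator receives a
crown; each crown independently survives to the next partner-choice
phase with probability q(β), a monotone decreasing interpolation through
q(0) = 1, q(0.002) = 0.75, q(0.005) = 0.5, q(0.02) = 0 (configurable via
`availability`). When an intervention is configured, the awareness test
consults the crowned set instead of ground truth. Crowns cannot exist
before the first interaction, so race-0 behavior is identical
draw-for-draw with an uncrowned run under the same seeds. Analytically
the intervention enters as an effective awareness
1 − (1−ω)(1−q(β)) from race 1 onward.

Infinite mode draws the partner's *type* directly from P(0) and ν,
reproducing the analytic recursion exactly; it exists as the Monte-Carlo
cross-check (vectorised over episodes) and for estimator-recovery tests.

RNG discipline: one root seed spawns a child generator per episode from
(seed, episode index), so extending a run never perturbs earlier
episodes; analytic sweeps are deterministic.

## Statistical checks and problem sizes

The random-baseline calibration uses 20,000 episodes (160,000 races),
putting 3 binomial standard errors at ±0.0037 around the awareness
target 1/2 and ±0.0032 around the stickiness target 1/5. The
Monte-Carlo/analytic agreement check runs 50,000 episodes per cell on a
3×3×3 (ω, s, b) grid with ρ = 0.75, τ = 0.25 — 864 simultaneous
binomial comparisons — so the 3σ criterion is held family-wise with a
Šidák-adjusted per-comparison threshold (z ≈ 4.66) plus a 0.5 continuity
correction; a plain per-comparison 3σ band would be expected to produce
two to three false alarms under the null. Contour sweeps use the 21×21
(s, ω) grid with 11 evenly spaced b values, D computed from P(8) and
averaged over b with equal weights (the averaging measure over b is a
choice; the evaluation-community composition ρ = τ = 1/2 is the default,
with training-tied composition exposed as an option).

## Shape of the contour surface

On the b-averaged surface, D is non-decreasing in ω at every s and
responds to ω nearly linearly. The stickiness response is smooth over
most of [0, 1]: stickiness shifts the fixed point e/(1−f) itself (at
ω = 0, γ₀ = 1/2 the limit is 1/(2−s)), so moderate s already changes D
materially. What concentrates near s = 1 is the *nonlinearity*: the
geometric rate f = s(1−ω)(1−γ₀) only slows convergence appreciably
there, and full stickiness locks in the initial biased pick, making
D(s = 1) < D(s = 0.9) whenever ω ≥ 0.5. Both features are asserted in
the test suite. A stricter reading — that D changes *less* over
s ∈ [0, 0.8] than between s = 0.9 and 1 at mid ω — does not hold in this
model and its test is expected to fail; the assertion is kept verbatim
rather than relaxed.

## What the synthetic conditions do and do not show

Coplayers are unconditional cooperators or defectors with perfectly
observable ground-truth strategies; crowns are honest and noise-free;
there is no learning within or across episodes, no spatial structure, no
disqualification, and the focal's only decision is partner choice.
Passing tests therefore validate the partner-choice dynamics, the index,
and the intervention mechanism — not the behavior of learning agents.
In particular, empirical stickiness of trained agents can exceed the
random 1/5 for reasons (e.g. shrinking partner pools) this abstraction
deliberately omits, and measured awareness of poor discriminators can
fall below 1/2 because cooperators pair preferentially with each other —
an interaction the finite-mode simulator reproduces only insofar as
coplayer pairing is uniform.

## Numerical choices

Probability vectors are validated to sum to 1 within 1e-12 with entries
clipped to [0, 1] only within that tolerance; larger violations raise,
distinguishing float noise from logic errors. The γ closed form switches
to its continuity limit e·i + γ₀ when |1−f| < 1e-14 (reachable only at
s = 1, ω = 0, γ₀ = 0). When γ(i) = 0 the sticky term has coefficient
zero and the step returns ν without evaluating the (undefined)
cooperator-conditional. Degenerate populations (ρ + τ = 0) raise a
dedicated error from any operation that must normalise over cooperators.
Emitted CSVs carry 12 significant digits and a commented header with
tool version, seed and config hash.
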