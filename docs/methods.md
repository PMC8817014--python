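# Methods

## The assignment problem

Two competing interventions A and B are available every period for a fixed
population of `obs` individuals followed over `T` periods.  Each individual
has a fixed pair of per-period treatment effects `(h_A, h_B)`; only the
response under the assigned arm is ever observed, so the individual contrast
`h_A − h_B` is unidentifiable from any single period.  When effects are
heterogeneous — and especially when the heterogeneity is unobserved — the
population-average contrast (the quantity an RCT estimates) can be a badly
biased guide to who should receive what.  The package implements and
compares two assignment strategies in this setting:

* **RCT baseline** — randomize 50/50 in period 1, estimate the average
  contrast by OLS of the period-1 response on an arm indicator, then assign
  everyone deterministically to the arm with the larger coefficient for all
  remaining periods (coefficient sign decides even when insignificant; a
  rule is required either way).
* **RITA** — recurrent individual treatment assignment: a probabilistic,
  rank-based policy updated every period per individual, described below.

A moderator variant of the baseline (OLS with an arm × observed-group
interaction, assignment by subgroup) is included as a comparator for the
case where part of the heterogeneity is observed.

## The RITA update

Let `rank_i ∈ {1, …, obs}` be individual *i*'s position in the pooled
distribution of period responses `Δy = y_t − y_{t−1}` (1 = smallest gain).
Each individual carries, per arm, an *individual mean rank* (IMR): the
running mean of the ranks received in the periods they were assigned that
arm, initialized at the neutral `obs/2`.  After an A-assignment with rank
`r`, the next-period probability of A is

    τ_A ← (r / obs) · (r / IMR_B) ^ (n_A − 1)

and symmetrically for B (τ_B updated the same way, τ_A = 1 − τ_B).  The
first factor (rescaled individual rank) reacts to this period's outcome; the
second compares it with the *other* arm's historical mean rank; the exponent
`n_A − 1` (assignments to the arm so far, counting the current one) is a
learning parameter that lets accumulated relative evidence dominate
exponentially.  Finally τ_A is clamped into `[λ_l, λ_u]` = [0.05, 0.95] so
exploration never ceases — the policy keeps probing the supposedly inferior
arm, which is what lets it track effects that could drift over time.

Numerical note: the drift factor can overflow a double for extreme
rank/IMR ratios at long horizons; the implementation lets it saturate to
infinity and relies on the clamp, which is exact in that regime.

The literal asymmetric B-branch variant (`PolicyConfig.eq10_literal=True`)
replaces the mirrored update with
`1 − τ_A = (1 − r/obs)·(IMR_A/r)^(n_B−1)`.  It moves probability mass away
from B precisely when B performs well, so it is not the default; it exists
only for side-by-side comparison.

### Design choices in the update

* **Order of operations.**  The IMR and count are updated *before* the
  probability, so the first assignment to an arm has exponent 0 and the
  update reduces to the rescaled rank — which is what makes the
  single-participant worked example in the test-suite arithmetic exact.
* **Tie-breaking.**  Ranks must form an exact permutation of `1..obs`
  (the `r/obs` rescaling assumes it).  Ties are broken by a seeded random
  order by default; a deterministic index-ordered alternative
  (`tie_rule="average"`) is available.  Under continuous outcome noise ties
  have probability zero, so the choice is immaterial in the shipped worlds.
* **Clamping** is applied every period to τ_A; with general bounds both
  arms' probabilities are kept inside `[λ_l, λ_u]` by intersecting the two
  constraints (with the default symmetric bounds this is automatic).
* No caliper/hysteresis against oscillating assignments is implemented;
  `PolicyConfig` is the natural home for such a hook.

## Simulated worlds

Effects follow the constrained decomposition `h_I = u_I · (1 + o_I)` with a
latent draw `u_I` (normal, or degenerate in world 1) and an observed-group
interaction `o_I = g/s_I` keyed on a binary label G split 50/50:

| world | arm A | arm B | character |
|---|---|---|---|
| 1 | 0.8 (constant) | 0.6 (constant) | no heterogeneity |
| 2 | N(0.8, 0.4) | N(0.6, 0.3) | latent only |
| 3 | N(0.7, 0.35)·(1+G/3.5) | N(0.5, 0.25)·(1+(1−G)/2.5) | latent + observed |
| 4 | N(0.7, 0.35)·(1+G/3.5) | N(0.7, 0.35)·(1+(1−G)/3.5) | equal means |

World 3's subgroup means are 0.9/0.7 for A and 0.5/0.7 for B (G=1/G=0),
giving overall means 0.8 and 0.6.  In world 4 both arms average 0.8, so the
population contrast carries no assignment information at all, while A is
better on average for G=1 and B for G=0.  Latent normals are deliberately
not truncated: truncation would shift the closed-form means that
`world_ate` guarantees and the tests verify by Monte Carlo.  The group
label is an exact half-split (then seeded shuffle) by default so "equally
distributed" holds exactly; iid Bernoulli assignment is available.

Per period, the observed response is `Δy = h_assigned + ε` with
`ε ~ N(0, 0.1)`; baseline outcomes are `y0 ~ N(10, 1)`.  The standard run
size is 1000 individuals over 60 periods.  Within-individual effects are
constant over time — the generator emulates stable unobserved heterogeneity
plus measurement noise, not dynamic effects, dropout, interference or
non-normal noise, so passing tests say nothing about those features of real
longitudinal data.

## Paired comparisons

`run_comparison` runs all policies against the bit-identical population and,
by default, the identical outcome-noise realisation per (individual,
period), with policy-internal randomness on independent named substreams of
the master seed.  Per-individual differences in cumulative gain
`(y_60 − y_0)` between policies are then exact paired counterfactuals of the
assignment decisions — in world 1, for example, each difference is exactly
−0.2 × (excess wrong assignments).  An `independent_noise` mode
(`shared_noise=False`) is available for fully independent runs; it leaves
means unchanged and only widens the per-individual differences.

## Summaries across replications

The headline statistics are the mean and median of the paired per-individual
gain difference (RITA − baseline) at the final period, plus the medians
within the two subgroups defined by each individual's ground-truth better
arm.  In world 4 the two arms' population means are exactly equal, so which
arm the baseline locks in after period 1 is a fair coin across replications,
and the labels "A-optimal"/"B-optimal" are not stable summaries.  Across
seeds the package therefore also aligns subgroups by whether an individual's
better arm matches the baseline's locked-in arm: the *aligned* subgroup is
the one the fixed rule already serves (it can only lose from exploration),
the *opposite* subgroup is the one only the adaptive policy can serve.  This
conditioning uses the design's symmetry, not any outcome value.

## Behaviour worth knowing about

* In world 1 the adaptive policy's share on A rises from ½ to a plateau of
  roughly 0.89 — below the 0.95 clamp.  The gap is a persistent "churn":
  with everyone concentrated on A, pooled ranks among A-assignees are close
  to uniform, and an individual whose current rank falls below their
  personal IMR_B has their probability collapse through the large learning
  exponent, triggering a one-period excursion to B before the drift factor
  pushes them back.  The typical individual receives the inferior arm about
  8 times in 60 periods (≈3 from the 5% exploration floor, the rest from
  the transient and this churn), a median paired loss of about −1.5 outcome
  units.  The same mechanism makes the subgroup already served by the fixed
  rule lose a median ≈ −1.9 in world 4.
* In world 4 the population share on A stays near ½ while individual
  probabilities polarize; the subgroup only the adaptive policy can serve
  gains a median ≈ +22, and the population mean paired gain is ≈ +11.6
  (SD ≈ 21) — the asymmetry that motivates the method: small losses for
  those a fixed rule already serves, large gains for those it cannot.
* The fraction of individuals on their personally better arm at the final
  period is higher under RITA than under the baseline in every replicated
  seed of worlds 2–4.

## Problem sizes used in the shipped checks

The test suite and the acceptance script replicate the paired comparison at
the standard size (1000 × 60) over 30 seeds per world, which gives
replication intervals for all summary statistics while keeping a full run in
well under a minute per world on one core.  Closed-form quantities
(subgroup means, worked-example arithmetic) are checked exactly; Monte-Carlo
checks of the generator use 10⁵ draws and 3-standard-error bands; oracle
equivalence of the full state trajectory is checked on panels of up to 6
individuals and 3 periods against an independently coded brute-force
transcription of the update rules.
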