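# Methods

## Model and procedure

Each of K ≥ 2 groups contributes independent right-censored observations
(Z_ij, δ_ij), where Z_ij = min(X_ij, Y_ij) for a latent survival time X and
an independent censoring time Y, and δ_ij = 1{X_ij ≤ Y_ij}. The survival
function of group *i* is F_i(t) = P(X > t) and its median is
θ_i = inf{t : F_i(t) ≤ 0.5}. The null hypothesis is θ_1 = … = θ_K; nothing
else about the distributions is assumed equal, so groups may differ in shape
and spread under the null.

The test proceeds in four steps:

1. Fit the Kaplan–Meier estimate F̂ to the pooled sample (all groups
   concatenated, labels ignored) and take its median θ̂₀.
2. For each group fit F̂_i and evaluate η_i = F̂_i(θ̂₀).
3. Estimate Var(η_i) by the composite estimate σ̂ᵢ² described below and set
   w_i = 1/σ̂ᵢ², h_i = w_i / Σ w_j.
4. Compute C = Σ w_i (η_i − Σ h_j η_j)² and the p-value from the upper tail
   of χ² with K − 1 degrees of freedom.

Under the null each η_i is asymptotically N(0.5, σ_i²), so C is the standard
inverse-variance-weighted heterogeneity statistic and the χ² reference
follows from Slutsky's theorem, given a consistent variance estimate. No
continuity or small-sample correction is applied to the p-value.

## The composite variance estimate

By the variance decomposition V(Y) = E[V(Y|X)] + V[E(Y|X)] applied to the
survival estimate, the Greenwood formula

    Greenwood(t) = F̂(t)² · Σ_{t_j ≤ t} d_j / (n_j (n_j − d_j))

approximates only the first term and therefore underestimates the variance
of η_i. Since a Cochran-type statistic increases in every weight, plugging
Greenwood alone into C yields an anti-conservative test — visibly so for
group sizes below about 30, where the simulation study here shows the
`greenwood_only` variant rejecting a true null at 8–10 % instead of 5 %.

The second term is estimated without resampling: take the group median θ̂ᵢ,
find the distinct uncensored time θ̂ᵢ₁ closest to it, and use

    [F̂ᵢ(θ̂ᵢ) − F̂ᵢ(θ̂ᵢ₁)]² / 2,

the sample variance of the two survival values bracketing the median — a
proxy for the between-resample variability a bootstrap would measure. The
term is of order nᵢ⁻², so the composite and Greenwood-only statistics
converge for large groups (and the composite statistic is never larger,
because its variances are never smaller).

## Conventions and degenerate inputs

* **Right continuity.** F̂ evaluated at an event time includes that jump, so
  the estimated median inf{t : F̂(t) ≤ 0.5} always lands on an event time.
  The comparison uses an absolute slack of 1e-12 so cumulative products that
  are exactly one half in real arithmetic are not pushed past the median by
  floating-point rounding.
* **Ties.** When an event and a censoring share a time, the event happens
  first: the censored subject still counts in that time's risk set.
* **Closest uncensored time.** The search excludes times equal to θ̂ᵢ itself
  (θ̂ᵢ is typically an uncensored time; including it would make the
  correction identically zero) and breaks exact distance ties toward the
  smaller time, for determinism. These two rules are this package's
  conventions where the method leaves the choice open.
* **Greenwood at zero survival.** Once F̂ hits 0 the term 1/(n_j − d_j) is
  undefined; the variance is returned as 0 (the F̂² factor annihilates the
  sum), matching the degenerate estimate it describes.
* **Missing correction.** If a group's median is undefined or it has no
  second uncensored time, the correction term is 0 (logged). Omitting an
  order n⁻² term only slightly inflates that group's weight.
* **Typed errors, not sentinels.** An undefined pooled median or a zero
  composite variance raises `DegenerateDataError`; downstream layers decide
  policy rather than propagating NaNs.
* **Time scale.** Times may be any finite reals. The composite statistic is
  invariant under positive affine time transforms (ranks and distance order
  both preserved); the Greenwood-only variant is invariant under any strictly
  increasing transform.

## What the simulation engine emulates

The engine reproduces a six-table study design with K = 4 groups at two
sample-size sets — n = (100, 150, 150, 200) and n = (20, 25, 25, 30) — and
nominal censoring rates p ∈ {0, 0.1, 0.2, 0.3}. Survival families per group:

| family | survival law | censoring law | median |
|---|---|---|---|
| uniform | U(−a/c, a/c) + θ | U(−a/c, a/c + (1−2p)/p) + θ | θ |
| exponential | θ + Exp(rate a) | θ + Exp(rate a·p/(1−p)) | θ + log 2 / a |
| lognormal | exp(θ + a·N(0,1)) | exp(θ + a·U(−2, −2 + 2/p)) | e^θ |

Null rows give all four groups equal medians (with equal or deliberately
unequal variances); power rows perturb one or two medians. Mixed rows pair
two groups each from two families, censoring matched to each group's family.
The log-uniform censoring law is interpreted as exp(θ + a·u) with u uniform,
mirroring the lognormal construction; for small p the implied censoring
probability P(U < Z), Z standard normal, is ≈ p. One power row prints its
lognormal parameters on the median scale; they are used as log-locations
log(10), log(14), consistent with the explicitly logged values of the
corresponding small-sample row. For the exponential family the realized
censoring fraction equals p exactly (competing exponentials); for the
uniform family it is w/(2W) with w, W the two support widths, which equals p
only when a/c = 1 — scenarios run with their printed parameters and are not
re-tuned, so uniform rows at nominal p = 0.3 are censored closer to 37 %.

Replicates are driven by per-replicate child streams of a single scenario
seed (`numpy` `SeedSequence.spawn`), so a scenario is bit-reproducible and
independent of execution order. A replicate on which any requested variant is
degenerate is redrawn from the next stream and counted (`degenerate_count`),
keeping the rejection denominator at the requested replicate count. At ≤ 30 %
censoring degeneracy is rare except in the heavily-censored mixed small-n
cells, where the count is surfaced for audit.

What the generator does **not** emulate: covariates, non-independent
censoring, ties from coarse measurement (all draws are continuous), staggered
entry, and group sizes outside the two printed sets. Passing tests therefore
say nothing about informative censoring or heavily tied data.

## Problem sizes used in the checks

The bundled test suite runs reduced Monte-Carlo modes chosen for quick
feedback: 2,000 replicates for calibration and power checks (Monte-Carlo SE
≈ 0.005 near a proportion of 0.05) and 5,000 for the type-I-error cells it
compares against published values at a ±0.015 tolerance;
`scripts/acceptance.py` uses 5,000 replicates per cell (SE ≈ 0.003–0.006).
The full-scale study (10,000 replicates per cell) is available through
`medsurv simulate --reps 10000` and takes tens of seconds per cell on one
CPU.

## Known limitations

* The χ² reference is asymptotic; the composite variance keeps the size near
  nominal down to n ≈ 20 per group in the simulated families, but nothing is
  guaranteed for very small groups or > 30 % censoring.
* Only the median is tested. The construction extends to other quantiles,
  but that extension is not implemented.
* Confidence intervals for the median difference, left truncation, interval
  censoring and competing risks are out of scope.
* In small, heavily censored cells the redraw policy for degenerate
  replicates (a design choice — alternatives include discarding or counting
  them as non-rejections) shifts empirical rejection proportions by a few
  tenths of a percentage point.
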