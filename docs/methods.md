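# Methods

## Measurement model

The cooperation-and-punishment model is a binary multinomial processing
tree. Per framing condition there are two trees, one per partner behavior,
each with four observable categories (participant cooperates/defects ×
punishes/does not). The participant's cooperation probability `C` is shared
across both trees of a condition: because choices are revealed
simultaneously, the participant cannot condition on the partner's choice.
Punishment after mutual cooperation is attributed entirely to the bias `b`;
after every other outcome the dedicated parameter (`P_Moral`,
`P_Hypocritical`, `P_Antisocial`) acts first and the bias applies to its
complement, giving punish-cell probability `P + (1−P)·b`. The model treats
punishment as binary; the invested amount (1–9 cents) carries no
information about the latent states and is not modelled.

Counts are pooled over participants within a condition
(aggregate-frequency MPT fitting, the standard convention). Individual
heterogeneity is therefore not modelled; see Limitations.

With two conditions the unconstrained model has 10 free parameters against
2 × 2 × 3 = 12 free category cells, so the goodness-of-fit statistic has
2 degrees of freedom; each cross-condition equality constraint adds one.

## Estimation

Fitting minimizes `G² = 2 Σ n ln(n/e)` over the free parameters, which is
equivalent to maximizing the multinomial likelihood. Numerical choices:

- **Scale.** Optimization runs on the log-odds scale (unbounded), avoiding
  box-constraint edge pathologies; estimates are back-transformed.
  Estimates within 1e-6 of 0 or 1 are flagged as boundary solutions.
- **Starts.** One method-of-moments start (cell proportions solved for the
  parameters, clipped to [0.01, 0.99]) plus random restarts with
  deterministic seeds; default 20 starts (`FitOptions.n_starts`). Large
  replication studies in the test-suite use 2–3 starts, which the moment
  start makes sufficient in practice. Ties between optima are broken by
  lowest G², then lexicographically smallest parameter vector.
- **Termination.** L-BFGS-B with `ftol = 1e-10` and `gtol = 1e-8`
  (configurable); non-convergence from every start raises with the
  optimizer trace.
- **Degenerate cells.** Zero observed counts use the `0·ln 0 = 0`
  convention. A positive count in a cell whose model probability is zero
  yields `G² = +inf` with a degeneracy warning rather than silent clamping.
- **Constraints.** Equality constraints are implemented by parameter
  sharing (one free slot bound to several condition/parameter positions),
  so ΔG² tests follow from refitting the restricted model; ΔG² values in
  `(−1e-6, 0)` from optimizer tolerance are clipped to zero and anything
  more negative raises.

Standard errors are square roots of the diagonal of the inverse observed
information (numerical Hessian of the negative multinomial log-likelihood
at the optimum, central differences with step `min(1e-5, distance to the
boundary / 4)`). At boundary estimates the observed-information argument
fails, so SEs are omitted with a warning. The SE method for the original
analyses is not publicly documented; observed information is the
conventional choice and its calibration is verified empirically (~95%
coverage of truth by estimate ± 1.96·SE across 200 simulated replications
of the 98 × 20 design).

Local identifiability is checked numerically: the Jacobian of the 12 free
category probabilities with respect to the free parameters, rank by SVD.
At generic interior points the unconstrained two-condition model has full
rank 10. Rank deficiency is reported, not raised — e.g. at `C = 0` the
moral-punishment parameter of that condition is confounded (no mass in the
cooperate cells) and is listed as a deficient direction.

## Inference and power

Goodness of fit refers G² to a central χ²(df). Cross-condition parameter
tests refer ΔG² to χ²(1) per added constraint; p-values are computed from
unrounded statistics. No multiple-testing correction is applied — the five
parameter tests are reported with raw p-values, mirroring standard practice
for this design; users needing familywise control should adjust downstream.

Cohen's w is `√(ΔG²/N)` where `N` is the total number of category
observations (participants × trials summed over both conditions, e.g.
98 × 20 = 1960). Power uses the noncentral χ² with `λ = N·w²`: the power of
the test is the noncentral upper-tail mass beyond the central critical
value at α. The sensitivity analysis solves `power(w) = 1 − β` for w by
bracketed root finding (tolerance 1e-10). This noncentrality convention is
the one used by standard power software for χ² tests and round-trips
exactly with the power function.

## Synthetic-data generator

The simulator emulates the study designs: by default 98 participants
(93 for the symmetric variant), 20 one-shot trials each, alternating
assignment to the moral/neutral arms by participant id, an exact random
half of partners cooperating per participant, payoffs 20/10/0/−10 cents
(temptation/reward/mutual-defection/sucker) from a 400-cent endowment, and
punishment at 1–9 cents cost with a tenfold deduction. Agents draw
cooperation Bernoulli(`C`) per trial and punish with the branch probability
of the realized outcome cell; in the symmetric design the partner punishes
the participant's unilateral defection every time it occurs, at a uniform
random cost.

Choices the design left open, decided once:

- **Punishment amounts.** The amount invested when punishing is not part of
  the binary model and its empirical distribution is unknown; it is drawn
  uniform on {1..9} by default and is pluggable per agent profile
  (`AgentProfile.punishment_amount_rule`). The partner's punishment cost in
  the symmetric design is likewise uniform {1..9}.
- **Random streams.** A single root seed spawns one child stream per
  participant, so enlarging the sample never perturbs earlier participants
  and the trial table is byte-identical across runs with the same seed.
- **Partner balances.** Partners change every trial; the displayed partner
  balance is the participant's balance plus a cosmetic ±10-cent jitter with
  no behavioral role, then updated within the trial by the payoff and
  punishment flows (every cent invested removes exactly ten from the
  punished party and one from the investor).

What the generator does *not* emulate: participant heterogeneity (all
agents in an arm share one parameter set — real data mix individuals),
partner faces and their perceptual effects, reaction times, info-button
usage, gender effects, and any trial-order or learning dynamics. Passing
recovery and calibration tests therefore shows that the estimator is
correct *under the model*, not that real data satisfy the model; with real
data the goodness-of-fit test itself is the check of the aggregation
assumption.

## Problem sizes used in validation

The test-suite validates the statistical claims at sizes chosen to make
Monte-Carlo error negligible relative to the tolerances: 200 replications
of the 98 × 20 design for bias (<0.02 per parameter) and 95%-interval
coverage (exact binomial 99% bounds), 500 null replications for type-I
error calibration at α = 0.05 (exact binomial 99% bounds), 10⁶ simulated
trials for generative/analytic agreement (3 multinomial SEs per cell), and
a full 0.05-step grid over the five free parameters of a one-condition
table (≈4.1 million points) as a brute-force optimization oracle.

## Limitations

- Aggregate-frequency fitting assumes homogeneous participants within a
  condition; hierarchical/latent-trait MPT variants are out of scope.
- Asymptotic χ² reference distributions are used throughout; with very
  small tree totals or boundary estimates the G²/ΔG² approximations
  degrade (boundary cases are flagged).
- The punishment magnitude is never modelled, only its presence.
- Confidence intervals are Wald-type from observed information; no
  profile-likelihood or bootstrap intervals are provided.
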