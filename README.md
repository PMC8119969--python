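# coopmpt

Multinomial processing tree (MPT) analysis of cooperation and costly
punishment in one-shot Prisoner's Dilemma experiments.

## The problem

In behavioral experiments on cooperation, participants play one-shot
simultaneous Prisoner's Dilemma rounds against preprogrammed partners (half
cooperate, half defect) and may afterwards spend 1–9 cents of their own
endowment to deduct ten times that amount from the partner. Raw punishment
rates conflate qualitatively different motives: punishing a partner who
defected against one's own cooperation (*moral* punishment), punishing a
defecting partner after defecting oneself (*hypocritical* punishment),
punishing a cooperating partner after defecting (*antisocial* punishment),
and an outcome-independent *bias* to punish. `coopmpt` is for researchers
who want to disentangle these motives with a formal measurement model, and
to compare them between experimental groups (for instance a moral-framing
versus a neutral-framing condition).

## The model

Each trial falls into one of two trees (partner cooperated / partner
defected) and one of four categories per tree (participant cooperated or
defected × punished or not). Five latent probabilities per condition
generate the category probabilities:

| partner | participant | punished | probability |
|---|---|---|---|
| cooperates | cooperates | yes | `C·b` |
| cooperates | cooperates | no  | `C·(1−b)` |
| cooperates | defects    | yes | `(1−C)·[P_A + (1−P_A)·b]` |
| cooperates | defects    | no  | `(1−C)·(1−P_A)·(1−b)` |
| defects    | cooperates | yes | `C·[P_M + (1−P_M)·b]` |
| defects    | cooperates | no  | `C·(1−P_M)·(1−b)` |
| defects    | defects    | yes | `(1−C)·[P_H + (1−P_H)·b]` |
| defects    | defects    | no  | `(1−C)·(1−P_H)·(1−b)` |

`C` is the probability of cooperating (independent of the partner's
simultaneous choice), `P_M`, `P_H`, `P_A` are the conditional probabilities
of moral, hypocritical and antisocial punishment, and `b` is the punishment
bias — the only source of punishment after mutual cooperation.

Parameters are estimated by maximum likelihood on the pooled category
counts, i.e. by minimizing the likelihood-ratio statistic
`G² = 2·Σ n·ln(n/e)`. Hypotheses about a parameter are tested by refitting
with that parameter constrained equal across conditions and referring
`ΔG² = G²_restricted − G²_full` to a χ² distribution with one degree of
freedom per constraint. Effect sizes use Cohen's `w = √(ΔG²/N)` with `N`
the total number of category observations; power and sensitivity analyses
use the noncentral χ² distribution with noncentrality `λ = N·w²`.

The package also ships the generative counterpart of the model: an
agent-based simulator of the full experiment (trial schedules, payoffs,
balances, both the asymmetric design and the symmetric design in which the
partner morally punishes the participant's unilateral defection), used for
parameter-recovery, coverage and type-I-error calibration studies.

## Worked example

Simulate a 98-participant, 20-trial experiment from the shipped example
configuration (synthetic generating values) and run the full analysis:

```sh
coopmpt simulate --design examples/exp1_design.json \
                 --params examples/exp1_params.json --seed 1 --out trials.csv
coopmpt report --trials trials.csv --label "simulated asymmetric-punishment experiment"
```

prints

```
=== simulated asymmetric-punishment experiment ===
Model: conditions=['moral', 'neutral'], constraints=none
Goodness of fit: G2(2) = 2.16, p = 0.340
  moral: C = 0.457 (SE 0.016), P_Moral = 0.495 (SE 0.043), P_Hypocritical = 0.239 (SE 0.041), P_Antisocial = 0.222 (SE 0.042), b = 0.167 (SE 0.024)
  neutral: C = 0.405 (SE 0.016), P_Moral = 0.293 (SE 0.043), P_Hypocritical = 0.194 (SE 0.037), P_Antisocial = 0.155 (SE 0.036), b = 0.119 (SE 0.023)

Cross-condition equality tests:
  C: dG2(1) = 5.41, p = 0.020, w = 0.05
  P_Moral: dG2(1) = 10.74, p = 0.001, w = 0.07
  P_Hypocritical: dG2(1) = 0.65, p = 0.420, w = 0.02
  P_Antisocial: dG2(1) = 1.41, p = 0.235, w = 0.03
  b: dG2(1) = 1.95, p = 0.163, w = 0.03
```

The base model fits (G² on 2 df, p = 0.340 — the two degrees of freedom are
the 12 free category cells minus 10 free parameters). The generating values
had a 0.20 gap in `P_Moral` between conditions, and the moral-punishment
equality test correctly rejects (ΔG²(1) = 10.74, p = 0.001); its effect size
is w = √(10.74/1960) = 0.07. The sensitivity of the design:

```sh
coopmpt power --alpha .05 --beta .05 --df 1 --n 1960
# minimal detectable w = 0.0814 (alpha=0.05, power=0.95, df=1, N=1960)
```

Real experimental data can be analyzed the same way by mapping them to the
trial CSV schema (one row per participant × trial with columns
`participant_id, condition, trial_index, partner_behavior,
participant_choice, punishment_investment, partner_punishment_cost,
participant_balance_after, partner_balance_after`; the balance columns are
optional on input).

The same functionality is available as a library — see
`coopmpt.run_paper_analysis`, `coopmpt.fit`, `coopmpt.compare_nested`,
`coopmpt.sensitivity_w` — and is documented in `docs/methods.md`.

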