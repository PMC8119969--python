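"""Simulation of one-shot Prisoner's Dilemma experiments with costly punishment.

Participants play 20 one-shot rounds against preprogrammed partners, half of
whom cooperate and half of whom defect, in a randomly permuted order.  After
seeing the simultaneous outcome, the participant may spend 1-9 cents to
deduct ten times that amount from the partner.  Participants are alternately
assigned to a moral-framing or a neutral-framing arm; agents in each arm
behave according to known latent MPT parameters, which makes the simulator
the generative counterpart of the measurement model and the basis for
parameter-recovery and calibration studies.

Two designs are supported: punishment only by the participant (asymmetric),
or additionally a partner who always morally punishes the participant's
unilateral defection with a random 1-9 cent investment (symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mpt_model import MptParameters, validate_params

PARTNER_BEHAVIORS = ("cooperate", "defect")

#: Trial-table column order (the CSV schema).
TRIAL_COLUMNS = (
    "participant_id",
    "condition",
    "trial_index",
    "partner_behavior",
    "participant_choice",
    "punishment_investment",
    "partner_punishment_cost",
    "participant_balance_after",
    "partner_balance_after",
)

#: Outcome cells of a round, from the participant's perspective.
OUTCOME_CELLS = (
    "mutual_cooperation",
    "participant_cooperates_partner_defects",
    "participant_defects_partner_cooperates",
    "mutual_defection",
)


class DesignError(ValueError):
    """Invalid experimental design."""


@dataclass(frozen=True)
class PayoffRule:
    """Prisoner's Dilemma payoff matrix (cents), symmetric in roles.

    Defaults: unilateral defection 20 > mutual cooperation 10 > mutual
    defection 0 > unilateral cooperation -10.
    """

    temptation: int = 20
    reward: int = 10
    punishment_outcome: int = 0
    sucker: int = -10

    def __post_init__(self):
        if not (self.temptation > self.reward > self.punishment_outcome > self.sucker):
            raise DesignError(
                "payoffs must satisfy temptation > reward > punishment_outcome > sucker"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """Structural parameters of one experiment.

    ``partner_punishes_unilateral_defection`` distinguishes the asymmetric
    design (False) from the symmetric design in which the partner always
    punishes the participant's unilateral defection (True).
    """

    n_participants: int = 98
    n_trials_per_participant: int = 20
    frac_partner_cooperate: float = 0.5
    endowment: int = 400
    punishment_cost_min: int = 1
    punishment_cost_max: int = 9
    punishment_multiplier: int = 10
    partner_punishes_unilateral_defection: bool = False
    framing_arms: tuple[str, ...] = ("moral", "neutral")
    payoffs: PayoffRule = field(default_factory=PayoffRule)

    def __post_init__(self):
        if self.n_participants < 1 or self.n_trials_per_participant < 1:
            raise DesignError("participant and trial counts must be positive")
        n_coop = self.frac_partner_cooperate * self.n_trials_per_participant
        if abs(n_coop - round(n_coop)) > 1e-9:
            raise DesignError(
                f"frac_partner_cooperate * n_trials = {n_coop} is not an integer"
            )
        if not (0 < self.punishment_cost_min <= self.punishment_cost_max):
            raise DesignError("punishment cost range must satisfy 0 < min <= max")


@dataclass(frozen=True)
class AgentProfile:
    """Ground-truth generating parameters plus the punishment-amount rule.

    The binary measurement model never constrains the invested amount;
    ``punishment_amount_rule(rng, size, lo, hi)`` supplies it when an agent
    punishes (uniform over the allowed cost range by default).
    """

    parameters: MptParameters
    punishment_amount_rule: Callable[[np.random.Generator, int, int, int], np.ndarray] | None = None

    def __post_init__(self):
        validate_params(self.parameters)

    def draw_amounts(self, rng: np.random.Generator, size: int, lo: int, hi: int) -> np.ndarray:
        if self.punishment_amount_rule is not None:
            return np.asarray(self.punishment_amount_rule(rng, size, lo, hi), dtype=int)
        return rng.integers(lo, hi + 1, size=size)


def partner_schedule(
    n_trials: int, frac_cooperate: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly random permutation of partner behaviors with an exact split.

    Exactly ``frac_cooperate * n_trials`` partners cooperate; the rest
    defect.  A non-integral split raises :class:`DesignError`.
    """
    n_coop = frac_cooperate * n_trials
    if abs(n_coop - round(n_coop)) > 1e-9:
        raise DesignError(f"frac_cooperate * n_trials = {n_coop} is not an integer")
    n_coop = int(round(n_coop))
    schedule = np.array(["cooperate"] * n_coop + ["defect"] * (n_trials - n_coop))
    return rng.permutation(schedule)


def apply_payoff(
    participant_choice: str, partner_behavior: str, rule: PayoffRule = PayoffRule()
) -> tuple[int, int]:
    """Payoff deltas (participant, partner) for one simultaneous round."""
    lookup = {
        ("cooperate", "cooperate"): (rule.reward, rule.reward),
        ("cooperate", "defect"): (rule.sucker, rule.temptation),
        ("defect", "cooperate"): (rule.temptation, rule.sucker),
        ("defect", "defect"): (rule.punishment_outcome, rule.punishment_outcome),
    }
    try:
        return lookup[(participant_choice, partner_behavior)]
    except KeyError:
        raise ValueError(
            f"invalid choices: {participant_choice!r} vs {partner_behavior!r}"
        ) from None


def outcome_cell(participant_choice: str, partner_behavior: str) -> str:
    coop_p = participant_choice == "cooperate"
    coop_o = partner_behavior == "cooperate"
    if coop_p and coop_o:
        return "mutual_cooperation"
    if coop_p:
        return "participant_cooperates_partner_defects"
    if coop_o:
        return "participant_defects_partner_cooperates"
    return "mutual_defection"


def punish_branch_probability(cell: str, params: MptParameters) -> float:
    """Probability that the participant punishes, given the round's outcome.

    After mutual cooperation only the bias ``b`` operates; after every other
    outcome the dedicated punishment parameter applies first and the bias
    mops up: ``P + (1 - P) * b``.
    """
    validate_params(params)
    b = params.b
    if cell == "mutual_cooperation":
        return b
    if cell == "participant_cooperates_partner_defects":
        p = params.P_Moral
    elif cell == "participant_defects_partner_cooperates":
        p = params.P_Antisocial
    elif cell == "mutual_defection":
        p = params.P_Hypocritical
    else:
        raise ValueError(f"unknown outcome cell: {cell!r}")
    return p + (1.0 - p) * b


def _participant_rng(seed: int, participant_id: int) -> np.random.Generator:
    # per-participant child stream: adding participants never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(participant_id,)))


def simulate_experiment(
    design: ExperimentDesign,
    profiles_by_condition: Mapping[str, AgentProfile],
    seed: int,
) -> pd.DataFrame:
    """Simulate the full experiment; one row per participant x trial.

    Participants are alternately assigned to the framing arms by id.  Per
    trial, the cooperation choice is Bernoulli(C), the punish decision is
    Bernoulli of :func:`punish_branch_probability` for the realized outcome,
    and the invested amount comes from the agent's amount rule.  Under the
    symmetric design the partner punishes exactly the participant's
    unilateral defection, at a uniformly random cost.  The result is fully
    reproducible from ``seed``.

    Account balances: each party starts at the endowment (the partner's
    displayed start is jittered by at most 10 cents, a purely cosmetic rule
    with no behavioral role), gains the round payoff, pays its own
    punishment investment, and loses ``punishment_multiplier`` times the
    opponent's investment.
    """
    missing = [arm for arm in design.framing_arms if arm not in profiles_by_condition]
    if missing:
        raise DesignError(f"missing agent profile(s) for condition(s): {missing}")

    n_trials = design.n_trials_per_participant
    lo, hi = design.punishment_cost_min, design.punishment_cost_max
    mult = design.punishment_multiplier
    payoff_lookup = {
        (c, p): apply_payoff(c, p, design.payoffs)
        for c in ("cooperate", "defect")
        for p in ("cooperate", "defect")
    }
    columns: dict[str, list] = {name: [] for name in TRIAL_COLUMNS}
    for pid in range(1, design.n_participants + 1):
        condition = design.framing_arms[(pid - 1) % len(design.framing_arms)]
        profile = profiles_by_condition[condition]
        par = profile.parameters
        rng = _participant_rng(seed, pid)

        partners = partner_schedule(n_trials, design.frac_partner_cooperate, rng)
        partner_coop = partners == "cooperate"
        choices_coop = rng.random(n_trials) < par.C

        punish_prob = np.empty(n_trials)
        cells = np.where(
            choices_coop & partner_coop, 0,
            np.where(choices_coop, 1, np.where(partner_coop, 2, 3)),
        )
        for i, cell in enumerate(OUTCOME_CELLS):
            mask = cells == i
            if mask.any():
                punish_prob[mask] = punish_branch_probability(cell, par)
        punished = rng.random(n_trials) < punish_prob
        investment = np.zeros(n_trials, dtype=int)
        if punished.any():
            investment[punished] = profile.draw_amounts(rng, int(punished.sum()), lo, hi)

        partner_cost = np.zeros(n_trials, dtype=int)
        if design.partner_punishes_unilateral_defection:
            betrayed = partner_coop & ~choices_coop
            if betrayed.any():
                partner_cost[betrayed] = rng.integers(lo, hi + 1, size=int(betrayed.sum()))

        choice_str = np.where(choices_coop, "cooperate", "defect")
        deltas = np.array(
            [payoff_lookup[(c, p)] for c, p in zip(choice_str, partners)]
        )
        participant_delta = deltas[:, 0] - investment - mult * partner_cost
        balance = design.endowment + np.cumsum(participant_delta)

        jitter = rng.integers(-10, 11, size=n_trials)
        balance_before = np.concatenate([[design.endowment], balance[:-1]])
        partner_balance = (
            balance_before + jitter + deltas[:, 1] - mult * investment - partner_cost
        )

        columns["participant_id"].append(np.full(n_trials, pid))
        columns["condition"].append(np.full(n_trials, condition, dtype=object))
        columns["trial_index"].append(np.arange(1, n_trials + 1))
        columns["partner_behavior"].append(partners)
        columns["participant_choice"].append(choice_str)
        columns["punishment_investment"].append(investment)
        columns["partner_punishment_cost"].append(partner_cost)
        columns["participant_balance_after"].append(balance)
        columns["partner_balance_after"].append(partner_balance)
    return pd.DataFrame(
        {name: np.concatenate(parts) for name, parts in columns.items()}
    )
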