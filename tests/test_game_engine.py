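"""Tests for the Prisoner's-Dilemma-with-punishment simulator."""

import numpy as np
import pytest

from coopmpt.game_engine import (
    AgentProfile,
    DesignError,
    ExperimentDesign,
    PayoffRule,
    apply_payoff,
    partner_schedule,
    punish_branch_probability,
    simulate_experiment,
)
from coopmpt.mpt_model import MptParameters, category_probabilities
from coopmpt.estimation import aggregate_trials


class TestPartnerSchedule:
    def test_exact_half_split(self, rng):
        schedule = partner_schedule(20, 0.5, rng)
        assert (schedule == "cooperate").sum() == 10
        assert (schedule == "defect").sum() == 10

    def test_degenerate_proportion_all_cooperate(self, rng):
        assert (partner_schedule(4, 1.0, rng) == "cooperate").all()

    def test_non_integral_split_rejected(self, rng):
        with pytest.raises(DesignError):
            partner_schedule(20, 0.33, rng)

    def test_positionally_uniform_permutation(self):
        """Across many schedules each position cooperates about half the time."""
        rng = np.random.default_rng(99)
        freq = np.mean(
            [(partner_schedule(20, 0.5, rng) == "cooperate") for _ in range(1000)],
            axis=0,
        )
        # three binomial standard errors at p = .5, n = 1000
        assert np.abs(freq - 0.5).max() < 3 * np.sqrt(0.25 / 1000)


class TestApplyPayoff:
    @pytest.mark.parametrize(
        "mine, theirs, expected",
        [
            ("cooperate", "cooperate", (10, 10)),
            ("cooperate", "defect", (-10, 20)),
            ("defect", "cooperate", (20, -10)),
            ("defect", "defect", (0, 0)),
        ],
    )
    def test_default_matrix(self, mine, theirs, expected):
        assert apply_payoff(mine, theirs) == expected

    def test_roles_are_symmetric(self):
        rule = PayoffRule()
        a = apply_payoff("cooperate", "defect", rule)
        b = apply_payoff("defect", "cooperate", rule)
        assert a == (b[1], b[0])

    def test_dilemma_ordering_enforced(self):
        with pytest.raises(DesignError):
            PayoffRule(temptation=5, reward=10, punishment_outcome=0, sucker=-10)

    def test_invalid_choice_rejected(self):
        with pytest.raises(ValueError):
            apply_payoff("cooperate", "waffle")


class TestPunishBranchProbability:
    def test_mutual_cooperation_is_bias_only(self, interior_params):
        p = interior_params.replace(b=0.2)
        assert punish_branch_probability("mutual_cooperation", p) == pytest.approx(0.2)

    def test_certain_moral_punishment_absorbs_bias(self, interior_params):
        p = interior_params.replace(P_Moral=1.0)
        assert punish_branch_probability(
            "participant_cooperates_partner_defects", p
        ) == pytest.approx(1.0)

    def test_mutual_defection_combines_parameter_and_bias(self):
        p = MptParameters(C=0.5, P_Moral=0.5, P_Hypocritical=0.3, P_Antisocial=0.5, b=0.1)
        assert punish_branch_probability("mutual_defection", p) == pytest.approx(0.37)

    def test_unknown_cell_rejected(self, interior_params):
        with pytest.raises(ValueError, match="unknown outcome cell"):
            punish_branch_probability("mutual_admiration", interior_params)


class TestSimulateExperiment:
    def test_row_count_matches_design(self, exp1_trials):
        assert len(exp1_trials) == 98 * 20

    def test_every_participant_sees_exact_partner_split(self, exp1_trials):
        per = exp1_trials.groupby("participant_id")["partner_behavior"].apply(
            lambda s: (s == "cooperate").sum()
        )
        assert (per == 10).all()

    def test_alternating_condition_assignment(self, exp1_trials):
        by_id = exp1_trials.groupby("participant_id")["condition"].first()
        assert by_id.loc[1] == "moral" and by_id.loc[2] == "neutral"
        assert (by_id.iloc[::2] == "moral").all()

    def test_deterministic_cooperator_profile(self, exp1_design):
        p = MptParameters(C=1.0, P_Moral=0.0, P_Hypocritical=0.0, P_Antisocial=0.0, b=0.0)
        profiles = {c: AgentProfile(p) for c in ("moral", "neutral")}
        trials = simulate_experiment(exp1_design, profiles, seed=5)
        assert (trials["participant_choice"] == "cooperate").all()
        assert (trials["punishment_investment"] == 0).all()

    def test_same_seed_reproduces_identical_table(self, exp1_design, interior_params):
        profiles = {c: AgentProfile(interior_params) for c in ("moral", "neutral")}
        a = simulate_experiment(exp1_design, profiles, seed=11)
        b = simulate_experiment(exp1_design, profiles, seed=11)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_adding_participants_preserves_earlier_streams(self, interior_params):
        profiles = {c: AgentProfile(interior_params) for c in ("moral", "neutral")}
        small = simulate_experiment(ExperimentDesign(n_participants=10), profiles, seed=3)
        large = simulate_experiment(ExperimentDesign(n_participants=20), profiles, seed=3)
        assert small.equals(large[large["participant_id"] <= 10].reset_index(drop=True))

    def test_balance_bookkeeping_conserves_punishment(self, exp1_design, interior_params):
        """Each cent invested removes tenfold from the partner and one from the investor."""
        profiles = {c: AgentProfile(interior_params) for c in ("moral", "neutral")}
        trials = simulate_experiment(exp1_design, profiles, seed=17)
        payoff = {
            ("cooperate", "cooperate"): 10, ("cooperate", "defect"): -10,
            ("defect", "cooperate"): 20, ("defect", "defect"): 0,
        }
        deltas = [
            payoff[(c, p)] - inv
            for c, p, inv in zip(
                trials["participant_choice"], trials["partner_behavior"],
                trials["punishment_investment"],
            )
        ]
        recomputed = (
            trials.assign(delta=deltas).groupby("participant_id")["delta"].cumsum() + 400
        )
        assert (recomputed == trials["participant_balance_after"]).all()

    def test_symmetric_design_partner_punishes_unilateral_defection_only(self, interior_params):
        design = ExperimentDesign(n_participants=40, partner_punishes_unilateral_defection=True)
        profiles = {c: AgentProfile(interior_params) for c in ("moral", "neutral")}
        trials = simulate_experiment(design, profiles, seed=23)
        betrayed = (trials["participant_choice"] == "defect") & (
            trials["partner_behavior"] == "cooperate"
        )
        assert (trials.loc[betrayed, "partner_punishment_cost"].between(1, 9)).all()
        assert (trials.loc[~betrayed, "partner_punishment_cost"] == 0).all()
        # the tenfold deduction reaches the participant's balance
        row = trials[betrayed].iloc[0]
        prev = trials[
            (trials["participant_id"] == row["participant_id"])
            & (trials["trial_index"] == row["trial_index"] - 1)
        ]
        before = 400 if prev.empty else int(prev["participant_balance_after"].iloc[0])
        assert row["participant_balance_after"] == (
            before + 20 - row["punishment_investment"] - 10 * row["partner_punishment_cost"]
        )

    def test_missing_profile_rejected(self, exp1_design, interior_params):
        with pytest.raises(DesignError, match="neutral"):
            simulate_experiment(exp1_design, {"moral": AgentProfile(interior_params)}, 1)

    def test_empirical_frequencies_match_category_probabilities(self, interior_params):
        """Generative/analytic agreement at 2000 participants, 3 SE per cell."""
        profiles = {c: AgentProfile(interior_params) for c in ("moral", "neutral")}
        design = ExperimentDesign(n_participants=2000)
        table = aggregate_trials(simulate_experiment(design, profiles, seed=31))
        probs = np.stack(
            [category_probabilities(interior_params)[t]
             for t in ("partner_cooperates", "partner_defects")]
        )
        for cond in table.conditions:
            n_tree = table.tree_totals(cond)[:, None]
            emp = table.counts(cond) / n_tree
            se = np.sqrt(probs * (1 - probs) / n_tree)
            assert (np.abs(emp - probs) <= 3 * se + 1e-12).all()
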