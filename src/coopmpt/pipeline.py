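"""End-to-end orchestration: simulate -> aggregate -> fit -> test -> report.

`run_paper_analysis` reproduces the standard analysis of a two-condition
framing experiment: fit the unconstrained two-condition model, report its
goodness of fit, then test each of the five latent parameters for equality
across conditions with ΔG², p and Cohen's w.  Reports serialize to JSON and
to a human-readable text table.

Trial data enter as a CSV with one row per participant x trial (see
``game_engine.TRIAL_COLUMNS``); external datasets in the same schema — e.g.
real experiments — are analyzed identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .estimation import FitOptions, FitResult, aggregate_trials, fit
from .game_engine import (
    TRIAL_COLUMNS,
    AgentProfile,
    ExperimentDesign,
    simulate_experiment,
)
from .inference import ComparisonResult, compare_nested
from .mpt_model import PARAM_NAMES, CategoryTable, CategoryTableError, ModelSpec, MptParameters

#: Reporting order for the cross-condition parameter tests.
TEST_ORDER = PARAM_NAMES  # (C, P_Moral, P_Hypocritical, P_Antisocial, b)


class TrialSchemaError(ValueError):
    """Trial CSV does not match the documented schema."""


def read_trials_csv(path) -> pd.DataFrame:
    """Read a trial table, validating the column schema."""
    trials = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    # balance columns are optional on input: aggregation never uses them
    missing = [c for c in missing if not c.endswith("_balance_after")
               and c != "partner_punishment_cost" and c != "trial_index"]
    if missing:
        raise TrialSchemaError(f"trial CSV is missing column(s): {missing}")
    return trials


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


@dataclass
class AnalysisReport:
    """Full analysis of one experiment: base fit plus five equality tests."""

    experiment_label: str
    base_fit: FitResult
    comparisons: list[ComparisonResult]
    design: dict = field(default_factory=dict)
    seed: int | None = None
    software: str = f"coopmpt {__version__}"

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment_label,
            "software": self.software,
            "seed": self.seed,
            "design": self.design,
            "base_fit": self.base_fit.to_dict(),
            "comparisons": [c.to_dict() for c in self.comparisons],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"=== {self.experiment_label} ===", self.base_fit.summary(), "",
                 "Cross-condition equality tests:"]
        lines += [f"  {c.summary()}" for c in self.comparisons]
        return "\n".join(lines)


def run_paper_analysis(
    trials: pd.DataFrame | str | Path,
    experiment_label: str = "experiment",
    options: FitOptions = FitOptions(),
    seed: int | None = None,
) -> AnalysisReport:
    """Aggregate trials, fit the unconstrained model, run all five tests.

    ``trials`` is a trial DataFrame or a CSV path in the documented schema
    and must contain exactly two framing conditions.  Cohen's w for every
    test uses the table's total category-observation count.
    """
    if isinstance(trials, (str, Path)):
        trials = read_trials_csv(trials)
    table = aggregate_trials(trials)
    if len(table.conditions) != 2:
        raise CategoryTableError(
            f"the cross-condition analysis requires exactly two framing "
            f"conditions, got {list(table.conditions)}"
        )
    spec = ModelSpec(conditions=table.conditions)
    base = fit(table, spec, options)
    comparisons = [
        compare_nested(table, spec, name, options, full_fit=base) for name in TEST_ORDER
    ]
    return AnalysisReport(
        experiment_label=experiment_label,
        base_fit=base,
        comparisons=comparisons,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plain-text (JSON) configuration for designs and agent profiles

def design_from_config(config: Mapping | str | Path) -> ExperimentDesign:
    """Build an ExperimentDesign from a JSON file or a mapping."""
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    config = dict(config)
    if "framing_arms" in config:
        config["framing_arms"] = tuple(config["framing_arms"])
    return ExperimentDesign(**config)


def profiles_from_config(config: Mapping | str | Path) -> dict[str, AgentProfile]:
    """Build per-condition agent profiles from ``{condition: {C: ..., ...}}``."""
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    return {
        cond: AgentProfile(parameters=MptParameters(**values))
        for cond, values in config.items()
    }


def simulate_to_frame(
    design_config: Mapping | str | Path,
    params_config: Mapping | str | Path,
    seed: int,
) -> pd.DataFrame:
    design = design_from_config(design_config)
    profiles = profiles_from_config(params_config)
    return simulate_experiment(design, profiles, seed)
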