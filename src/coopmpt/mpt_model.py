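"""Multinomial processing tree (MPT) model of cooperation and costly punishment.

The model describes behavior in a one-shot simultaneous Prisoner's Dilemma
with a costly punishment option.  Each trial falls into one of two trees,
determined by the partner's (preprogrammed) behavior, and within each tree
into one of four observable categories: the participant cooperates or
defects, and punishes or does not punish.  Five latent probabilities per
framing condition generate the category probabilities:

``C``
    probability that the participant cooperates (independent of the
    partner's choice, which is revealed simultaneously);
``P_Moral``
    conditional probability of punishing a partner who defected against the
    participant's cooperation (moral punishment);
``P_Hypocritical``
    conditional probability of punishing a defecting partner after the
    participant also defected (hypocritical punishment);
``P_Antisocial``
    conditional probability of punishing a cooperating partner after the
    participant defected (antisocial punishment);
``b``
    an outcome-independent bias to punish; the only source of punishment
    after mutual cooperation.

Punishment after a non-mutual-cooperation outcome occurs either through the
outcome-specific parameter or, failing that, through the bias, so the
punish-cell probability is ``P + (1 - P) * b``.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PARAM_NAMES: tuple[str, ...] = ("C", "P_Moral", "P_Hypocritical", "P_Antisocial", "b")

#: Tree labels, keyed by the partner's behavior.
TREES: tuple[str, ...] = ("partner_cooperates", "partner_defects")

#: Fixed category (cell) order within each tree.
CELLS: tuple[str, ...] = (
    "cooperate_punished",
    "cooperate_unpunished",
    "defect_punished",
    "defect_unpunished",
)

BOUNDARY_TOL = 1e-6


class ParameterError(ValueError):
    """A latent probability lies outside [0, 1]."""


@dataclass(frozen=True)
class MptParameters:
    """One set of latent model probabilities (one framing condition)."""

    C: float
    P_Moral: float
    P_Hypocritical: float
    P_Antisocial: float
    b: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "MptParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def replace(self, **kwargs: float) -> "MptParameters":
        return replace(self, **kwargs)


def validate_params(params: MptParameters) -> tuple[MptParameters, frozenset[str]]:
    """Check that every probability lies in [0, 1].

    Returns the parameters unchanged together with the set of names sitting
    on the boundary (within ``BOUNDARY_TOL`` of 0 or 1).  Boundary values are
    legal but invalidate the usual standard-error computation, so callers can
    react to the flags.

    Raises
    ------
    ParameterError
        Naming the offending parameter if any value is outside [0, 1] or not
        finite.
    """
    boundary: set[str] = set()
    for name in PARAM_NAMES:
        value = getattr(params, name)
        if not np.isfinite(value) or value < 0.0 or value > 1.0:
            raise ParameterError(f"parameter {name}={value!r} is outside [0, 1]")
        if value < BOUNDARY_TOL or value > 1.0 - BOUNDARY_TOL:
            boundary.add(name)
    return params, frozenset(boundary)


def tree_probabilities(C, P_Moral, P_Hypocritical, P_Antisocial, b) -> np.ndarray:
    """Category probabilities for both trees, vectorized over parameter arrays.

    Returns an array of shape ``(..., 2, 4)``; axis -2 follows ``TREES`` and
    axis -1 follows ``CELLS``.  Accepts scalars or broadcastable arrays, which
    lets a grid search evaluate millions of parameter points in one call.
    """
    C, PM, PH, PA, b = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (C, P_Moral, P_Hypocritical, P_Antisocial, b))
    )
    pc = np.stack(
        [
            C * b,
            C * (1.0 - b),
            (1.0 - C) * (PA + (1.0 - PA) * b),
            (1.0 - C) * (1.0 - PA) * (1.0 - b),
        ],
        axis=-1,
    )
    pd_ = np.stack(
        [
            C * (PM + (1.0 - PM) * b),
            C * (1.0 - PM) * (1.0 - b),
            (1.0 - C) * (PH + (1.0 - PH) * b),
            (1.0 - C) * (1.0 - PH) * (1.0 - b),
        ],
        axis=-1,
    )
    return np.stack([pc, pd_], axis=-2)


def category_probabilities(params: MptParameters) -> dict[str, np.ndarray]:
    """Map latent parameters to the 8 observable category probabilities.

    Returns ``{tree: probabilities}`` with four probabilities per tree in
    ``CELLS`` order; each tree's probabilities sum to one.
    """
    validate_params(params)
    probs = tree_probabilities(*params.as_array())
    return {tree: probs[i] for i, tree in enumerate(TREES)}


class CategoryTableError(ValueError):
    """Malformed category-count table."""


class CategoryTable:
    """Per-condition 8-cell response frequencies, the model's sufficient statistic.

    Counts are pooled over participants within each framing condition
    (aggregate-frequency MPT fitting).  Cell ordering is fixed by ``TREES``
    and ``CELLS``.
    """

    def __init__(self, counts: Mapping[str, np.ndarray | Sequence[Sequence[float]]],
                 conditions: Sequence[str] | None = None):
        """``counts`` maps condition label -> array of shape (2, 4)."""
        if conditions is None:
            conditions = list(counts)
        self.conditions: tuple[str, ...] = tuple(conditions)
        self._counts: dict[str, np.ndarray] = {}
        for cond in self.conditions:
            arr = np.asarray(counts[cond], dtype=float)
            if arr.shape != (2, 4):
                raise CategoryTableError(
                    f"condition {cond!r}: expected a (2, 4) count array, got {arr.shape}"
                )
            if (arr < 0).any():
                raise CategoryTableError(f"condition {cond!r}: negative count")
            self._counts[cond] = arr

    def counts(self, condition: str) -> np.ndarray:
        return self._counts[condition]

    def tree_total(self, condition: str, tree: str) -> float:
        return float(self._counts[condition][TREES.index(tree)].sum())

    def tree_totals(self, condition: str) -> np.ndarray:
        return self._counts[condition].sum(axis=1)

    @property
    def n_total(self) -> float:
        """Total number of category observations (trials) across conditions."""
        return float(sum(arr.sum() for arr in self._counts.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CategoryTable):
            return NotImplemented
        return self.conditions == other.conditions and all(
            np.array_equal(self._counts[c], other._counts[c]) for c in self.conditions
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cond, tree, cell, self._counts[cond][i, j])
            for cond in self.conditions
            for i, tree in enumerate(TREES)
            for j, cell in enumerate(CELLS)
        ]
        return pd.DataFrame(rows, columns=["condition", "tree", "cell", "count"])

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CategoryTable":
        required = {"condition", "tree", "cell", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise CategoryTableError(f"missing columns: {sorted(missing)}")
        conditions = list(dict.fromkeys(frame["condition"]))
        counts = {c: np.zeros((2, 4)) for c in conditions}
        for _, row in frame.iterrows():
            try:
                i, j = TREES.index(row["tree"]), CELLS.index(row["cell"])
            except ValueError as exc:
                raise CategoryTableError(f"unknown tree/cell label: {exc}") from None
            counts[row["condition"]][i, j] += row["count"]
        return cls(counts, conditions)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CategoryTable":
        return cls.from_frame(pd.read_csv(path_or_buf))

    def to_json(self) -> str:
        obj = {
            "conditions": list(self.conditions),
            "trees": list(TREES),
            "cells": list(CELLS),
            "counts": {c: self._counts[c].tolist() for c in self.conditions},
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CategoryTable":
        obj = json.loads(text)
        return cls(obj["counts"], obj["conditions"])

    def __repr__(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_string(buf, index=False)
        return f"CategoryTable(n_total={self.n_total:g})\n{buf.getvalue()}"


@dataclass(frozen=True)
class ModelSpec:
    """A (possibly constrained) multi-condition model.

    ``constraints`` lists parameter names whose value is shared (equal)
    across all conditions.  With two conditions the unconstrained model has
    10 free parameters against 12 free category cells, hence 2 degrees of
    freedom; each equality constraint adds one.
    """

    conditions: tuple[str, ...] = ("moral", "neutral")
    constraints: frozenset[str] = frozenset()

    def __post_init__(self):
        unknown = set(self.constraints) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter(s) in constraints: {sorted(unknown)}")
        if len(self.conditions) < 1:
            raise CategoryTableError("at least one condition required")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def free_labels(self) -> tuple[str, ...]:
        """Ordered labels of free parameter slots (shared slots listed once)."""
        labels = []
        for name in PARAM_NAMES:
            if name in self.constraints and self.n_conditions > 1:
                labels.append(name)
            else:
                labels.extend(f"{name}[{c}]" for c in self.conditions)
        return tuple(labels)

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_labels)

    @property
    def n_free_cells(self) -> int:
        # each tree has 4 cells with one sum-to-one restriction
        return 2 * 3 * self.n_conditions

    @property
    def df(self) -> int:
        return self.n_free_cells - self.n_free_parameters

    def slot_index(self) -> dict[tuple[str, str], int]:
        """Map (condition, parameter name) -> index in the free vector."""
        labels = self.free_labels
        index: dict[tuple[str, str], int] = {}
        for name in PARAM_NAMES:
            for cond in self.conditions:
                if name in self.constraints and self.n_conditions > 1:
                    index[(cond, name)] = labels.index(name)
                else:
                    index[(cond, name)] = labels.index(f"{name}[{cond}]")
        return index

    def expand(self, free_values: Sequence[float]) -> dict[str, MptParameters]:
        """Free parameter vector -> per-condition parameter sets."""
        idx = self.slot_index()
        free_values = np.asarray(free_values, dtype=float)
        return {
            cond: MptParameters(**{n: float(free_values[idx[(cond, n)]]) for n in PARAM_NAMES})
            for cond in self.conditions
        }

    def with_constraint(self, parameter_name: str) -> "ModelSpec":
        return ModelSpec(self.conditions, self.constraints | {parameter_name})


def _g_squared_cells(observed: np.ndarray, expected: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    impossible = (expected == 0) & (observed > 0)
    if impossible.any():
        warnings.warn(
            "observed counts in structurally impossible cells (expected = 0); "
            "G^2 is infinite — boundary degeneracy",
            RuntimeWarning,
            stacklevel=3,
        )
        return float("inf")
    mask = observed > 0
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def expected_counts(
    table: CategoryTable, params: Mapping[str, MptParameters] | MptParameters
) -> dict[str, np.ndarray]:
    """Model-expected cell counts: tree total x category probability."""
    if isinstance(params, MptParameters):
        params = {cond: params for cond in table.conditions}
    out: dict[str, np.ndarray] = {}
    for cond in table.conditions:
        probs = tree_probabilities(*params[cond].as_array())
        out[cond] = table.tree_totals(cond)[:, None] * probs
    return out


def g_squared(
    table: CategoryTable,
    params: Mapping[str, MptParameters] | MptParameters | Mapping[str, np.ndarray],
) -> float:
    """Likelihood-ratio goodness-of-fit statistic G^2 = 2 sum n ln(n/e).

    ``params`` is either latent parameters (one set, or one per condition) or
    precomputed expected counts keyed by condition.  Zero observed cells
    contribute nothing (0 ln 0 = 0); a positive observed count in a cell with
    zero expected probability yields +infinity with a degeneracy warning.
    """
    if not isinstance(params, MptParameters):
        first = next(iter(params.values()))
        if not isinstance(first, MptParameters):
            expected = {c: np.asarray(params[c], dtype=float) for c in table.conditions}
            return sum(
                _g_squared_cells(table.counts(c), expected[c]) for c in table.conditions
            )
    expected = expected_counts(table, params)
    return sum(_g_squared_cells(table.counts(c), expected[c]) for c in table.conditions)


def multinomial_loglik(
    table: CategoryTable, params: Mapping[str, MptParameters] | MptParameters
) -> float:
    """Multinomial log-likelihood (up to the count-only constant)."""
    if isinstance(params, MptParameters):
        params = {cond: params for cond in table.conditions}
    total = 0.0
    for cond in table.conditions:
        probs = tree_probabilities(*params[cond].as_array())
        n = table.counts(cond)
        mask = n > 0
        with np.errstate(divide="ignore"):
            logp = np.log(probs)
        if np.isneginf(logp[mask]).any():
            return float("-inf")
        total += float(np.sum(n[mask] * logp[mask]))
    return total
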