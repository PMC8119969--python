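"""Maximum-likelihood estimation of the cooperation-and-punishment model.

Fitting minimizes the G^2 statistic (equivalently, maximizes the multinomial
likelihood) over the free parameters of a :class:`~coopmpt.mpt_model.ModelSpec`.
Equality constraints across conditions are implemented by parameter sharing,
so nested-model tests follow directly from refitting.  Optimization runs on
the log-odds scale, which removes the [0, 1] box constraint; multiple
deterministic starts (a method-of-moments start plus random restarts) guard
against local optima.  Standard errors come from the inverse observed
information of the multinomial log-likelihood at the optimum and are omitted
with a warning when an estimate sits on the boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .mpt_model import (
    CELLS,
    PARAM_NAMES,
    TREES,
    BOUNDARY_TOL,
    CategoryTable,
    CategoryTableError,
    ModelSpec,
    MptParameters,
    g_squared,
    tree_probabilities,
)

_REQUIRED_TRIAL_COLUMNS = (
    "participant_id",
    "condition",
    "partner_behavior",
    "participant_choice",
    "punishment_investment",
)


def aggregate_trials(
    trials: pd.DataFrame, conditions: Sequence[str] | None = None
) -> CategoryTable:
    """Reduce a trial table to per-condition 8-cell category counts.

    A trial is classified "punished" iff its punishment investment is
    positive.  ``conditions`` fixes the condition order; by default the
    canonical ("moral", "neutral") order is used when those are the labels,
    otherwise order of first appearance.
    """
    missing = [c for c in _REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise CategoryTableError(f"trial table is missing column(s): {missing}")
    labels = list(dict.fromkeys(trials["condition"]))
    if conditions is None:
        conditions = ("moral", "neutral") if set(labels) == {"moral", "neutral"} else labels
    unknown = set(labels) - set(conditions)
    if unknown:
        raise CategoryTableError(f"unknown condition label(s): {sorted(unknown)}")

    counts = {cond: np.zeros((2, 4)) for cond in conditions}
    if len(trials):
        bad = set(trials["partner_behavior"]) - {"cooperate", "defect"}
        bad |= set(trials["participant_choice"]) - {"cooperate", "defect"}
        if bad:
            raise CategoryTableError(f"unknown behavior label(s): {sorted(bad)}")
        tree_i = (trials["partner_behavior"] == "defect").astype(int)
        punished = (trials["punishment_investment"] > 0).astype(int)
        cell_j = 2 * (trials["participant_choice"] == "defect").astype(int) + (1 - punished)
        grouped = (
            pd.DataFrame({"condition": trials["condition"], "i": tree_i, "j": cell_j})
            .value_counts()
            .reset_index(name="n")
        )
        for _, row in grouped.iterrows():
            counts[row["condition"]][row["i"], row["j"]] += row["n"]
    return CategoryTable(counts, conditions)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls.

    ``n_starts`` counts the moment-based start plus random restarts; start
    seeds are deterministic functions of ``start_seed``.
    """

    n_starts: int = 20
    start_seed: int = 0
    gtol: float = 1e-8
    ftol: float = 1e-10
    max_iter: int = 500
    compute_se: bool = True


@dataclass
class FitResult:
    """Outcome of one (possibly constrained) model fit."""

    model: ModelSpec
    estimates: dict[str, MptParameters]
    standard_errors: dict[str, float]
    g2: float
    df: int
    p_value: float
    converged: bool
    n_total: float
    boundary_parameters: tuple[str, ...] = ()
    optimizer_trace: list[dict] = field(default_factory=list)

    @property
    def free_values(self) -> np.ndarray:
        idx = self.model.slot_index()
        out = np.empty(self.model.n_free_parameters)
        for (cond, name), k in idx.items():
            out[k] = getattr(self.estimates[cond], name)
        return out

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.model.conditions),
            "constraints": sorted(self.model.constraints),
            "estimates": {c: p.as_dict() for c, p in self.estimates.items()},
            "standard_errors": self.standard_errors,
            "g2": self.g2,
            "df": self.df,
            "p_value": self.p_value,
            "converged": self.converged,
            "n_total": self.n_total,
            "boundary_parameters": list(self.boundary_parameters),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        lines = [
            f"Model: conditions={list(self.model.conditions)}, "
            f"constraints={sorted(self.model.constraints) or 'none'}",
            f"Goodness of fit: G2({self.df}) = {self.g2:.2f}, p = {self.p_value:.3f}",
        ]
        for cond in self.model.conditions:
            p = self.estimates[cond]
            parts = []
            for name in PARAM_NAMES:
                label = name if name in self.model.constraints else f"{name}[{cond}]"
                se = self.standard_errors.get(label)
                se_txt = f" (SE {se:.3f})" if se is not None and np.isfinite(se) else ""
                parts.append(f"{name} = {getattr(p, name):.3f}{se_txt}")
            lines.append(f"  {cond}: " + ", ".join(parts))
        if self.boundary_parameters:
            lines.append(f"  boundary estimates: {list(self.boundary_parameters)}")
        return "\n".join(lines)


class FitError(RuntimeError):
    """Optimization failed to converge from every start."""


def _moment_start(table: CategoryTable, spec: ModelSpec) -> np.ndarray:
    """Closed-form method-of-moments start on the probability scale."""

    def per_condition(n: np.ndarray) -> dict[str, float]:
        tot = n.sum(axis=1)
        tot = np.where(tot > 0, tot, 1.0)
        coop = (n[0, 0] + n[0, 1] + n[1, 0] + n[1, 1]) / (tot[0] + tot[1])
        b = n[0, 0] / max(n[0, 0] + n[0, 1], 1.0)
        def deconf(q):  # q = P + (1-P) b  =>  P = (q-b)/(1-b)
            return (q - b) / (1.0 - b) if b < 1.0 else 0.0
        q_a = n[0, 2] / max(n[0, 2] + n[0, 3], 1.0)
        q_m = n[1, 0] / max(n[1, 0] + n[1, 1], 1.0)
        q_h = n[1, 2] / max(n[1, 2] + n[1, 3], 1.0)
        return {
            "C": coop,
            "P_Moral": deconf(q_m),
            "P_Hypocritical": deconf(q_h),
            "P_Antisocial": deconf(q_a),
            "b": b,
        }

    moments = {cond: per_condition(table.counts(cond)) for cond in spec.conditions}
    idx = spec.slot_index()
    start = np.zeros(spec.n_free_parameters)
    hits = np.zeros(spec.n_free_parameters)
    for (cond, name), k in idx.items():
        start[k] += moments[cond][name]
        hits[k] += 1
    return np.clip(start / hits, 0.01, 0.99)


def _objective(theta: np.ndarray, table: CategoryTable, spec: ModelSpec) -> float:
    p = special.expit(theta)
    probs = {}
    idx = spec.slot_index()
    total = 0.0
    for cond in spec.conditions:
        vals = [p[idx[(cond, name)]] for name in PARAM_NAMES]
        pr = tree_probabilities(*vals)
        n = table.counts(cond)
        e = table.tree_totals(cond)[:, None] * pr
        mask = n > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            total += 2.0 * float(np.sum(n[mask] * np.log(n[mask] / e[mask])))
    return total


def fit(
    table: CategoryTable,
    spec: ModelSpec | None = None,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Maximum-likelihood fit by direct G^2 minimization.

    Runs ``options.n_starts`` L-BFGS-B minimizations on the log-odds scale
    (one moment-based start, the rest random but seed-deterministic), keeps
    the best optimum (ties broken by lexicographically smallest parameter
    vector), and reports estimates, observed-information standard errors,
    G^2, degrees of freedom and the chi-square p-value.
    """
    if spec is None:
        spec = ModelSpec(conditions=table.conditions)
    for cond in spec.conditions:
        if (table.tree_totals(cond) <= 0).any():
            raise CategoryTableError(f"condition {cond!r} has an empty tree")

    starts = [_moment_start(table, spec)]
    rng = np.random.default_rng(options.start_seed)
    for _ in range(max(options.n_starts - 1, 0)):
        starts.append(rng.uniform(0.05, 0.95, size=spec.n_free_parameters))

    trace: list[dict] = []
    best: tuple[float, tuple, optimize.OptimizeResult] | None = None
    for i, p0 in enumerate(starts):
        res = optimize.minimize(
            _objective,
            special.logit(p0),
            args=(table, spec),
            method="L-BFGS-B",
            options={
                "gtol": options.gtol,
                "ftol": options.ftol,
                "maxiter": options.max_iter,
            },
        )
        p_hat = special.expit(res.x)
        trace.append(
            {
                "start": i,
                "g2": float(res.fun),
                "converged": bool(res.success),
                "n_iter": int(res.nit),
            }
        )
        key = (float(res.fun), tuple(np.round(p_hat, 12)))
        if res.success and (best is None or key < best[:2]):
            best = (key[0], key[1], res)
    if best is None:
        raise FitError(f"no start converged; trace: {trace}")

    g2_val, p_tuple, res = best
    free_values = np.array(p_tuple)
    g2_val = max(g2_val, 0.0)
    estimates = spec.expand(free_values)
    df = spec.df
    p_value = float(stats.chi2.sf(g2_val, df)) if df > 0 else float("nan")

    labels = spec.free_labels
    boundary = tuple(
        labels[k]
        for k in range(len(labels))
        if free_values[k] < BOUNDARY_TOL or free_values[k] > 1 - BOUNDARY_TOL
    )
    if options.compute_se:
        ses = _observed_information_se(table, spec, free_values, boundary)
    else:
        ses = {lab: float("nan") for lab in labels}

    return FitResult(
        model=spec,
        estimates=estimates,
        standard_errors=ses,
        g2=float(g2_val),
        df=df,
        p_value=p_value,
        converged=True,
        n_total=table.n_total,
        boundary_parameters=boundary,
        optimizer_trace=trace,
    )


def _neg_loglik(p: np.ndarray, table: CategoryTable, spec: ModelSpec) -> float:
    idx = spec.slot_index()
    total = 0.0
    for cond in spec.conditions:
        vals = [p[idx[(cond, name)]] for name in PARAM_NAMES]
        pr = tree_probabilities(*vals)
        n = table.counts(cond)
        mask = n > 0
        with np.errstate(divide="ignore"):
            logp = np.log(pr)
        if np.isneginf(logp[mask]).any():
            return float("inf")
        total -= float(np.sum(n[mask] * logp[mask]))
    return total


def _observed_information_se(
    table: CategoryTable,
    spec: ModelSpec,
    p_hat: np.ndarray,
    boundary: tuple[str, ...],
    step: float = 1e-5,
) -> dict[str, float]:
    labels = spec.free_labels
    if boundary:
        warnings.warn(
            f"boundary estimate(s) {list(boundary)}: observed-information "
            "standard errors are not valid and are omitted",
            RuntimeWarning,
            stacklevel=2,
        )
        return {lab: float("nan") for lab in labels}
    k = len(p_hat)
    h = np.minimum(step, np.minimum(p_hat, 1 - p_hat) / 4)
    H = np.empty((k, k))
    f0 = _neg_loglik(p_hat, table, spec)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                pp = p_hat.copy(); pp[i] += h[i]
                pm = p_hat.copy(); pm[i] -= h[i]
                H[i, i] = (_neg_loglik(pp, table, spec) - 2 * f0 + _neg_loglik(pm, table, spec)) / h[i] ** 2
            else:
                ppp = p_hat.copy(); ppp[[i, j]] += [h[i], h[j]]
                ppm = p_hat.copy(); ppm[i] += h[i]; ppm[j] -= h[j]
                pmp = p_hat.copy(); pmp[i] -= h[i]; pmp[j] += h[j]
                pmm = p_hat.copy(); pmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (
                    _neg_loglik(ppp, table, spec)
                    - _neg_loglik(ppm, table, spec)
                    - _neg_loglik(pmp, table, spec)
                    + _neg_loglik(pmm, table, spec)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; standard errors omitted",
                      RuntimeWarning, stacklevel=2)
        se = np.full(k, np.nan)
    return {lab: float(s) for lab, s in zip(labels, se)}


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Numerical local-identifiability diagnostic at one parameter point."""

    jacobian_rank: int
    expected_rank: int
    deficient_directions: tuple[str, ...]
    evaluation_point: dict[str, MptParameters]

    @property
    def identified(self) -> bool:
        return self.jacobian_rank == self.expected_rank


def check_identifiability(
    spec: ModelSpec,
    point: Mapping[str, MptParameters],
    perturbation: float = 1e-6,
) -> IdentifiabilityReport:
    """Rank of the Jacobian of free category probabilities w.r.t. free parameters.

    The model is locally identifiable at ``point`` iff the Jacobian of the
    free cells (three per tree, the fourth being determined by normalization)
    has full column rank.  Rank deficiency is reported, not raised; the
    parameters spanning the (numerical) null space are listed as confounded.
    """
    idx = spec.slot_index()
    labels = spec.free_labels
    p0 = np.empty(len(labels))
    for (cond, name), k in idx.items():
        p0[k] = getattr(point[cond], name)

    def free_cells(p: np.ndarray) -> np.ndarray:
        out = []
        for cond in spec.conditions:
            vals = [p[idx[(cond, name)]] for name in PARAM_NAMES]
            out.append(tree_probabilities(*vals)[:, :3].ravel())
        return np.concatenate(out)

    J = np.empty((spec.n_free_cells, len(labels)))
    for k in range(len(labels)):
        pp = p0.copy(); pp[k] += perturbation
        pm = p0.copy(); pm[k] -= perturbation
        J[:, k] = (free_cells(pp) - free_cells(pm)) / (2 * perturbation)

    s = np.linalg.svd(J, compute_uv=False)
    tol = max(J.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)
    tol = max(tol, 1e-9)
    rank = int(np.sum(s > tol))
    deficient: tuple[str, ...] = ()
    if rank < len(labels):
        _, _, vt = np.linalg.svd(J)
        null = vt[rank:]
        weight = np.abs(null).max(axis=0)
        deficient = tuple(
            lab for lab, w in zip(labels, weight) if w > 0.1 * weight.max()
        )
    return IdentifiabilityReport(
        jacobian_rank=rank,
        expected_rank=len(labels),
        deficient_directions=deficient,
        evaluation_point=dict(point),
    )
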