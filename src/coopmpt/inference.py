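"""Hypothesis tests, effect sizes and chi-square power analysis.

Cross-condition hypotheses about a latent parameter are tested by comparing
the unrestricted model with a nested model in which that parameter is
constrained to be equal across framing conditions; the fit difference
ΔG² is asymptotically chi-square with one degree of freedom per added
constraint.  Effect sizes use Cohen's w = sqrt(ΔG²/N) with N the total
number of category observations.  Power calculations use the noncentral
chi-square distribution with noncentrality λ = N·w².
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .estimation import FitOptions, FitResult, fit
from .mpt_model import CategoryTable, ModelSpec


def goodness_of_fit(fit_result: FitResult) -> tuple[float, int, float]:
    """(G², df, p) of a converged fit; p is the upper chi-square tail."""
    if not fit_result.converged:
        raise ValueError("goodness of fit requires a converged fit")
    if fit_result.df <= 0:
        raise ValueError(f"df must be positive, got {fit_result.df}")
    p = float(stats.chi2.sf(fit_result.g2, fit_result.df))
    return fit_result.g2, fit_result.df, p


def effect_size_w(delta_g2: float, n_total: float) -> float:
    """Cohen's w for a ΔG² test: w = sqrt(ΔG² / N)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if delta_g2 < 0:
        raise ValueError("delta_g2 must be nonnegative")
    return float(np.sqrt(delta_g2 / n_total))


def power_chisq(w: float, n_total: float, df: int, alpha: float) -> float:
    """Power of the chi-square test at effect size w and N observations.

    Noncentrality λ = N·w²; power is the probability mass of the noncentral
    chi-square beyond the central critical value at ``alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_total <= 0 or df <= 0 or w < 0:
        raise ValueError("n_total and df must be positive, w nonnegative")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    lam = n_total * w * w
    if lam == 0.0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, lam))


def sensitivity_w(alpha: float, power: float, df: int, n_total: float) -> float:
    """Minimal detectable Cohen's w at given alpha, power, df and N.

    Solves ``power_chisq(w, N, df, alpha) = power`` for w by bracketed root
    finding to a tolerance of 1e-10 in w.
    """
    if not (0 < alpha < power < 1):
        raise ValueError("need 0 < alpha < power < 1")
    hi = 0.1
    while power_chisq(hi, n_total, df, alpha) < power:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("failed to bracket the sensitivity root")
    return float(
        optimize.brentq(
            lambda w: power_chisq(w, n_total, df, alpha) - power,
            0.0,
            hi,
            xtol=1e-10,
        )
    )


@dataclass
class ComparisonResult:
    """One nested-model test of cross-condition parameter equality."""

    parameter_tested: str
    delta_g2: float
    df: int
    p_value: float
    w: float
    n_total: float
    full_fit: FitResult | None = None
    restricted_fit: FitResult | None = None

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter_tested,
            "delta_g2": self.delta_g2,
            "df": self.df,
            "p_value": self.p_value,
            "w": self.w,
            "n_total": self.n_total,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        p_txt = "< 0.001" if self.p_value < 0.001 else f"= {self.p_value:.3f}"
        return (
            f"{self.parameter_tested}: dG2({self.df}) = {self.delta_g2:.2f}, "
            f"p {p_txt}, w = {self.w:.2f}"
        )


def compare_nested(
    table: CategoryTable,
    spec_full: ModelSpec,
    parameter_name: str,
    options: FitOptions = FitOptions(),
    full_fit: FitResult | None = None,
) -> ComparisonResult:
    """Test equality of one parameter across conditions by ΔG².

    Fits the full model (or reuses ``full_fit``) and the model with
    ``parameter_name`` constrained equal across conditions; ΔG² is referred
    to the central chi-square with df equal to the number of added
    constraints (1 for two conditions).  Tiny negative differences from
    optimizer tolerance are clipped to zero.
    """
    if full_fit is None:
        full_fit = fit(table, spec_full, options)
    spec_restricted = spec_full.with_constraint(parameter_name)
    restricted = fit(table, spec_restricted, options)
    df = full_fit.model.n_free_parameters - spec_restricted.n_free_parameters
    delta = restricted.g2 - full_fit.g2
    if delta < -1e-6:
        raise RuntimeError(
            f"restricted model fits better than the full model (dG2 = {delta:.3g}); "
            "optimization failure"
        )
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, df)) if df > 0 else float("nan")
    return ComparisonResult(
        parameter_tested=parameter_name,
        delta_g2=float(delta),
        df=int(df),
        p_value=p,
        w=effect_size_w(delta, table.n_total),
        n_total=table.n_total,
        full_fit=full_fit,
        restricted_fit=restricted,
    )
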