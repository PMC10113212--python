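"""Maximum-likelihood fitting of the 2-HT model under equality restrictions.

The joint likelihood is product-multinomial: two independent multinomials
(culprit-present / culprit-absent trees) per condition.  Free parameters are
optimised on the logit scale with multiple restarts; standard errors come
from the inverse expected (Fisher) information of the product-multinomial
likelihood evaluated at the maximum-likelihood estimates, reported directly
on the probability scale.

Inference helpers: the likelihood-ratio statistic G² with its chi-square
p-value, nested-model ΔG² comparisons, Cohen's w, and a chi-square
sensitivity analysis (minimum detectable w at given alpha, power and N).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .model import (
    CATEGORY_ORDER,
    PARAM_NAMES,
    ResponseTable,
    ValidationError,
    category_probability_array,
)
from .restrictions import RestrictionSet

__all__ = [
    "FitResult",
    "NestedTest",
    "FitError",
    "fit_model",
    "compare_nested",
    "cohens_w",
    "sensitivity_w",
    "degrees_of_freedom",
]

_BOUNDARY_TOL = 1e-5


class FitError(RuntimeError):
    """Fitting failed structurally (bad inputs or non-nested comparison)."""


def degrees_of_freedom(tables: Sequence[ResponseTable], restrictions: RestrictionSet) -> int:
    """Residual degrees of freedom: 2 free categories per tree, 2 trees per
    condition, minus the number of free parameter groups."""
    df = 4 * len(tables) - restrictions.n_free
    if df < 0:
        raise ValidationError(
            f"over-parameterized model: {restrictions.n_free} free parameters for "
            f"{4 * len(tables)} independent categories"
        )
    return df


@dataclass
class FitResult:
    """Result of a joint maximum-likelihood fit."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    g_squared: float
    df: int
    p_value: float
    expected: dict[str, pd.Series]
    converged: bool
    n_total: int
    restrictions: RestrictionSet
    seed: int | None = None
    n_restarts: int = 0
    boundary: frozenset = field(default_factory=frozenset)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.restrictions.labels

    def estimate(self, param: str, label: str) -> float:
        """Estimate for ``param`` in condition ``label`` (fixed or free)."""
        group = self.restrictions.group_of(label, param)
        if group in self.restrictions.fixed:
            return self.restrictions.fixed[group]
        return self.estimates[group]

    def se(self, param: str, label: str) -> float:
        group = self.restrictions.group_of(label, param)
        if group in self.restrictions.fixed:
            return 0.0
        return self.standard_errors[group]

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "log_likelihood": self.log_likelihood,
            "g_squared": self.g_squared,
            "df": self.df,
            "p_value": self.p_value,
            "expected": {k: v.to_dict() for k, v in self.expected.items()},
            "converged": self.converged,
            "n_total": self.n_total,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "boundary": sorted(self.boundary),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        lines = [
            f"G2({self.df}) = {self.g_squared:.2f}, p = {self.p_value:.3f}, "
            f"N = {self.n_total}, converged = {self.converged}",
            "parameter estimates (SE):",
        ]
        for group in self.restrictions.free_groups:
            flag = " [boundary]" if group in self.boundary else ""
            lines.append(
                f"  {group} = {self.estimates[group]:.4f} "
                f"({self.standard_errors[group]:.4f}){flag}"
            )
        for group, value in self.restrictions.fixed.items():
            lines.append(f"  {group} = {value:.4f} (fixed)")
        return "\n".join(lines)


@dataclass(frozen=True)
class NestedTest:
    """Likelihood-ratio comparison of two nested fits."""

    delta_g_squared: float
    df: int
    p_value: float
    w: float

    def to_dict(self) -> dict:
        return {
            "delta_g_squared": self.delta_g_squared,
            "df": self.df,
            "p_value": self.p_value,
            "w": self.w,
        }

    def summary(self) -> str:
        return (
            f"dG2({self.df}) = {self.delta_g_squared:.2f}, "
            f"p = {self.p_value:.3f}, w = {self.w:.2f}"
        )


class _Likelihood:
    """Pre-indexed product-multinomial likelihood for a set of tables."""

    def __init__(self, tables: Sequence[ResponseTable], restrictions: RestrictionSet):
        labels = [t.condition.label for t in tables]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate condition labels {labels}")
        if set(labels) != set(restrictions.labels):
            raise ValidationError(
                f"restrictions cover {restrictions.labels}, tables are {tuple(labels)}"
            )
        self.tables = list(tables)
        self.labels = tuple(labels)
        self.restrictions = restrictions
        self.free_groups = restrictions.free_groups
        C = len(tables)
        self.counts = np.array([t.as_array() for t in tables])  # (C, 6)
        self.tree_totals = np.array(
            [[t.condition.n_culprit_present, t.condition.n_culprit_absent] for t in tables],
            dtype=float,
        )
        self.cell_totals = np.repeat(self.tree_totals, 3, axis=1)  # (C, 6)
        self.lineup_sizes = np.full(C, 6.0)
        group_index = {g: j for j, g in enumerate(self.free_groups)}
        self.idx = np.zeros((C, 4), dtype=int)
        self.free_mask = np.zeros((C, 4), dtype=bool)
        self.fixed_theta = np.zeros((C, 4))
        for i, lab in enumerate(labels):
            for j, p in enumerate(PARAM_NAMES):
                g = restrictions.group_of(lab, p)
                if g in restrictions.fixed:
                    self.fixed_theta[i, j] = restrictions.fixed[g]
                else:
                    self.free_mask[i, j] = True
                    self.idx[i, j] = group_index[g]

    def theta_conditions(self, theta_free: np.ndarray) -> np.ndarray:
        theta = self.fixed_theta.copy()
        theta[self.free_mask] = theta_free[self.idx[self.free_mask]]
        return theta

    def probabilities(self, theta_free: np.ndarray) -> np.ndarray:
        return category_probability_array(
            self.theta_conditions(theta_free), self.lineup_sizes
        )

    def nll(self, eta: np.ndarray) -> float:
        probs = self.probabilities(expit(eta))
        return -float(np.sum(self.counts * np.log(np.clip(probs, 1e-300, None))))


def _saturated_loglik(counts: np.ndarray, cell_totals: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(cell_totals > 0, counts / np.where(cell_totals > 0, cell_totals, 1), 0.0)
        terms = np.where(counts > 0, counts * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(terms.sum())


def fit_model(
    tables: Sequence[ResponseTable],
    restrictions: RestrictionSet,
    *,
    seed: int | None = 0,
    n_restarts: int = 10,
    tol: float = 1e-10,
    compute_se: bool = True,
) -> FitResult:
    """Jointly fit the 2-HT model to one table per condition.

    Optimisation runs on the logit scale, starting once from 0.5 for every
    parameter plus ``n_restarts`` seeded random starts; the best likelihood
    is retained.

    Parameters
    ----------
    seed
        Seed for the restart generator (required for reproducible fits).
    n_restarts
        Number of random restarts in addition to the deterministic start.
    tol
        Convergence tolerance on the log-likelihood.
    compute_se
        Skip the information-matrix step when False (e.g. in simulation
        studies that only need G²).
    """
    if not tables:
        raise ValidationError("need at least one response table")
    lik = _Likelihood(tables, restrictions)
    df = degrees_of_freedom(tables, restrictions)
    n_free = len(lik.free_groups)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_free)]
    for _ in range(n_restarts):
        starts.append(logit(rng.uniform(0.05, 0.95, size=n_free)))

    best = None
    if n_free == 0:
        best_eta = np.zeros(0)
        best_nll = lik.nll(best_eta)
        converged = True
    else:
        for x0 in starts:
            res = optimize.minimize(
                lik.nll,
                x0,
                method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": tol, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        best_eta = best.x
        best_nll = float(best.fun)
        converged = bool(best.success and np.isfinite(best_nll))

    theta_free = expit(best_eta)
    probs = lik.probabilities(theta_free)
    loglik = -best_nll
    expected_cells = probs * lik.cell_totals
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lik.counts > 0, lik.counts / np.where(expected_cells > 0, expected_cells, np.nan), 1.0)
        terms = np.where(lik.counts > 0, lik.counts * np.log(ratio), 0.0)
    if np.any(np.isnan(terms)):
        g_squared = float("inf")
        converged = False
        warnings.warn("observed count in a cell with zero expected count; G2 is infinite")
    else:
        g_squared = max(float(2.0 * terms.sum()), 0.0)

    if df > 0:
        p_value = float(stats.chi2.sf(g_squared, df)) if np.isfinite(g_squared) else 0.0
    else:
        p_value = 1.0 if g_squared < 1e-6 else 0.0

    estimates = {g: float(theta_free[j]) for j, g in enumerate(lik.free_groups)}
    boundary = frozenset(
        g for g, v in estimates.items() if v < _BOUNDARY_TOL or v > 1 - _BOUNDARY_TOL
    )

    if compute_se and n_free > 0:
        ses = _expected_information_se(lik, theta_free, boundary)
    else:
        ses = {g: float("nan") for g in lik.free_groups}

    expected = {
        lab: pd.Series(expected_cells[i], index=list(CATEGORY_ORDER), name=lab)
        for i, lab in enumerate(lik.labels)
    }
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        log_likelihood=loglik,
        g_squared=g_squared,
        df=df,
        p_value=p_value,
        expected=expected,
        converged=converged,
        n_total=int(lik.counts.sum()),
        restrictions=restrictions,
        seed=seed,
        n_restarts=n_restarts,
        boundary=boundary,
    )


def _expected_information_se(
    lik: _Likelihood, theta_free: np.ndarray, boundary: frozenset
) -> dict[str, float]:
    """SEs from the inverse expected information, on the probability scale.

    The Jacobian of the stacked category probabilities with respect to the
    free parameter vector is differenced numerically (central differences,
    one-sided at the [0, 1] boundary).
    """
    n_free = theta_free.size
    h = 1e-6
    J = np.zeros((lik.counts.size, n_free))
    for j in range(n_free):
        lo = max(theta_free[j] - h, 0.0)
        hi = min(theta_free[j] + h, 1.0)
        tp, tm = theta_free.copy(), theta_free.copy()
        tp[j], tm[j] = hi, lo
        J[:, j] = (lik.probabilities(tp) - lik.probabilities(tm)).ravel() / (hi - lo)
    probs = lik.probabilities(theta_free).ravel()
    weights = lik.cell_totals.ravel() / np.clip(probs, 1e-12, None)
    info = J.T @ (J * weights[:, None])
    ses: dict[str, float] = {}
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        ok = np.all(diag > 0)
    except np.linalg.LinAlgError:
        ok = False
    for j, g in enumerate(lik.free_groups):
        if not ok or g in boundary:
            ses[g] = float("nan")
        else:
            ses[g] = float(np.sqrt(diag[j]))
    if boundary or not ok:
        warnings.warn(
            "standard errors unavailable for boundary estimates or singular information"
        )
    return ses


def cohens_w(delta_g_squared: float, n_total: int) -> float:
    """Cohen's effect size w = sqrt(ΔG² / N)."""
    if n_total <= 0:
        raise ValidationError(f"n_total={n_total!r} must be positive")
    if delta_g_squared < 0:
        warnings.warn(f"negative statistic {delta_g_squared!r} clamped to 0")
        delta_g_squared = 0.0
    return float(np.sqrt(delta_g_squared / n_total))


def compare_nested(base: FitResult, restricted: FitResult) -> NestedTest:
    """ΔG² likelihood-ratio test of a restricted model against its base.

    The restricted model's restriction set must strictly refine the base
    model's, and both must have been fitted to the same tables.
    """
    if restricted.n_total != base.n_total or set(restricted.labels) != set(base.labels):
        raise FitError("models were not fitted to the same tables")
    if not restricted.restrictions.refines(base.restrictions):
        raise FitError("restricted model does not refine the base model (not nested)")
    df = restricted.df - base.df
    if df <= 0:
        raise FitError(
            "models have identical numbers of free parameters; comparison requires "
            "a strictly more restrictive model"
        )
    delta = restricted.g_squared - base.g_squared
    if delta < 0:
        if delta > -1e-6:
            warnings.warn(f"tiny negative dG2 {delta!r} clamped to 0 (optimizer noise)")
            delta = 0.0
        else:
            raise FitError(
                f"dG2 = {delta}: restricted model fits better than base; "
                "re-fit with more restarts"
            )
    p = float(stats.chi2.sf(delta, df))
    return NestedTest(delta, df, p, cohens_w(delta, base.n_total))


def sensitivity_w(alpha: float, power: float, n_total: int, df: int = 1) -> float:
    """Minimum effect size w detectable at given alpha, power, N and df.

    Solves for the noncentrality of the noncentral chi-square whose mass
    beyond the central critical value equals ``power``, then converts to
    Cohen's w.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValidationError("alpha and power must lie strictly between 0 and 1")
    if n_total <= 0 or df < 1:
        raise ValidationError("n_total must be positive and df >= 1")
    crit = stats.chi2.ppf(1 - alpha, df)
    if power <= alpha:
        return 0.0

    def gap(lam: float) -> float:
        return stats.ncx2.sf(crit, df, lam) - power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise FitError("no noncentrality solution found below 1e8")
    lam = optimize.brentq(gap, 1e-12, hi, xtol=1e-12)
    return float(np.sqrt(lam / n_total))
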