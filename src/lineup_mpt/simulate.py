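"""Synthetic eyewitness and mock-witness data.

Generates datasets with exactly the statistical structure the estimator
assumes: independent multinomial draws per tree from the model's category
probabilities, and multinomial mock-witness choices with a controllable
suspect bias.  A single seeded :class:`numpy.random.Generator` drives every
draw, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fairness import ChoiceDistribution
from .fit import FitResult, compare_nested, fit_model
from .model import (
    ConditionSpec,
    ModelParameters,
    ResponseTable,
    ValidationError,
    predict_category_probabilities,
)
from .restrictions import RestrictionSet

__all__ = [
    "SimulationDesign",
    "condition_for_participants",
    "simulate_eyewitness",
    "simulate_mock_witness",
    "parameter_recovery_study",
    "RecoverySummary",
]


def condition_for_participants(
    label: str,
    n_participants: int,
    lineups_per_participant: int = 4,
    lineup_format: str = "simultaneous",
    filler_type: str = "morphed",
) -> ConditionSpec:
    """Condition spec for a design in which each participant sees
    ``lineups_per_participant`` lineups, split evenly between culprit-present
    and culprit-absent."""
    if lineups_per_participant % 2 != 0:
        raise ValidationError("lineups_per_participant must be even (equal split)")
    per_tree = n_participants * lineups_per_participant // 2
    return ConditionSpec(label, lineup_format, filler_type, per_tree, per_tree)


@dataclass(frozen=True)
class SimulationDesign:
    """Conditions (spec + generating parameters) plus the seed for one run."""

    conditions: tuple[tuple[ConditionSpec, ModelParameters], ...]
    lineups_per_participant: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(tuple(c) for c in self.conditions))
        if self.lineups_per_participant % 2 != 0:
            raise ValidationError("lineups_per_participant must be even (equal split)")
        labels = [spec.label for spec, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate condition labels {labels}")


def simulate_eyewitness(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> list[ResponseTable]:
    """Draw one six-category response table per condition.

    Culprit-present and culprit-absent counts are independent multinomials
    with the model's predicted category probabilities.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    tables = []
    for spec, params in design.conditions:
        probs = predict_category_probabilities(params)
        cp = rng.multinomial(spec.n_culprit_present, probs.cp())
        ca = rng.multinomial(spec.n_culprit_absent, probs.ca())
        tables.append(ResponseTable(spec, *cp.tolist(), *ca.tolist()))
    return tables


def simulate_mock_witness(
    k: int,
    suspect_bias: float,
    n_witnesses: int,
    seed: int | np.random.Generator = 0,
    suspect_index: int = 0,
) -> ChoiceDistribution:
    """Multinomial mock-witness choices over ``k`` lineup members.

    Each witness picks the suspect with probability ``(1 + bias) / (k + bias)``
    and otherwise uniformly among the fillers; ``bias = 0`` is the perfectly
    fair lineup.
    """
    if k < 2:
        raise ValidationError(f"k={k!r} must be >= 2")
    if suspect_bias < 0:
        raise ValidationError(f"suspect_bias={suspect_bias!r} must be >= 0")
    if n_witnesses < 0:
        raise ValidationError(f"n_witnesses={n_witnesses!r} must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.full(k, 1.0 / (k + suspect_bias))
    p[suspect_index] = (1.0 + suspect_bias) / (k + suspect_bias)
    counts = rng.multinomial(n_witnesses, p)
    return ChoiceDistribution(tuple(counts.tolist()), suspect_index)


@dataclass
class RecoverySummary:
    """Per-group Monte-Carlo summary of a parameter-recovery study."""

    truth: dict[str, float]
    mean_estimate: dict[str, float]
    bias: dict[str, float]
    empirical_sd: dict[str, float]
    rmse: dict[str, float]
    mean_se: dict[str, float]
    coverage_2se: dict[str, float]
    n_replications: int
    n_failed: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "truth": self.truth,
            "mean_estimate": self.mean_estimate,
            "bias": self.bias,
            "empirical_sd": self.empirical_sd,
            "rmse": self.rmse,
            "mean_se": self.mean_se,
            "coverage_2se": self.coverage_2se,
            "n_replications": self.n_replications,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }


def parameter_recovery_study(
    design: SimulationDesign,
    restrictions: RestrictionSet,
    replications: int,
    seed: int = 0,
    n_restarts: int = 2,
) -> RecoverySummary:
    """Repeatedly simulate from ``design`` and refit under ``restrictions``.

    The generating value of a free group is taken from its member slots,
    which must agree (a group whose slots have different generating values
    has no single truth to recover).
    """
    if replications < 1:
        raise ValidationError("replications must be >= 1")
    by_label = {spec.label: params for spec, params in design.conditions}
    truth: dict[str, float] = {}
    for group in restrictions.free_groups:
        values = {
            getattr(by_label[lab], param) for lab, param in restrictions.members(group)
        }
        if len(values) != 1:
            raise ValidationError(
                f"group {group!r} spans slots with different generating values {values}"
            )
        truth[group] = values.pop()

    rng = np.random.default_rng(seed)
    estimates: dict[str, list[float]] = {g: [] for g in truth}
    ses: dict[str, list[float]] = {g: [] for g in truth}
    covered: dict[str, list[bool]] = {g: [] for g in truth}
    n_failed = 0
    for _ in range(replications):
        tables = simulate_eyewitness(design, rng=rng)
        try:
            fit = fit_model(
                tables,
                restrictions,
                seed=int(rng.integers(2**31)),
                n_restarts=n_restarts,
            )
        except Exception:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        for g in truth:
            est, se = fit.estimates[g], fit.standard_errors[g]
            estimates[g].append(est)
            ses[g].append(se)
            if np.isfinite(se):
                covered[g].append(abs(est - truth[g]) <= 2 * se)

    def summarise(fn) -> dict[str, float]:
        return {g: float(fn(g)) for g in truth}

    return RecoverySummary(
        truth=truth,
        mean_estimate=summarise(lambda g: np.mean(estimates[g])),
        bias=summarise(lambda g: np.mean(estimates[g]) - truth[g]),
        empirical_sd=summarise(lambda g: np.std(estimates[g], ddof=1) if len(estimates[g]) > 1 else 0.0),
        rmse=summarise(lambda g: np.sqrt(np.mean((np.array(estimates[g]) - truth[g]) ** 2))),
        mean_se=summarise(lambda g: np.nanmean(ses[g]) if ses[g] else float("nan")),
        coverage_2se=summarise(lambda g: np.mean(covered[g]) if covered[g] else float("nan")),
        n_replications=replications,
        n_failed=n_failed,
        seed=seed,
    )
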