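"""Two-high-threshold (2-HT) lineup identification model.

The model is a multinomial processing tree with two trees, one for
culprit-present and one for culprit-absent lineups.  Four latent-process
probabilities govern the observable response categories:

* ``dP`` — detection of the culprit's presence (culprit-present tree only),
* ``b``  — biased selection of the suspect without memory,
* ``g``  — guessing-based selection among the lineup members,
* ``dA`` — detection of the culprit's absence (culprit-absent tree only).

Guessing-based selection hits the suspect with probability ``1/k`` for a
lineup of ``k`` members and one of the fillers otherwise.  Each tree emits
three categories (suspect identification, filler identification, rejection),
giving six observable categories per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "CATEGORY_ORDER",
    "LINEUP_FORMATS",
    "FILLER_TYPES",
    "ValidationError",
    "ModelParameters",
    "ConditionSpec",
    "CategoryDistribution",
    "ResponseTable",
    "predict_category_probabilities",
    "category_probability_array",
    "expected_counts",
    "read_response_tables",
    "write_response_tables",
]

#: Latent-process parameter names, in canonical order.
PARAM_NAMES = ("dP", "b", "g", "dA")

#: Canonical category order used for every array, table and CSV column set.
CATEGORY_ORDER = (
    "cp_suspect",
    "cp_filler",
    "cp_reject",
    "ca_suspect",
    "ca_filler",
    "ca_reject",
)

LINEUP_FORMATS = ("simultaneous", "sequential")
FILLER_TYPES = ("morphed", "non-morphed")

_CSV_COLUMNS = ("condition", "lineup_format", "filler_type") + CATEGORY_ORDER


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


@dataclass(frozen=True)
class ModelParameters:
    """Latent-process probabilities for one condition plus the lineup size.

    ``lineup_size`` is a design constant (never estimated); it only enters
    the model through the ``1/k`` guessing split.
    """

    dP: float
    b: float
    g: float
    dA: float
    lineup_size: int = 6

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValidationError(f"parameter {name}={value!r} must lie in [0, 1]")
        k = self.lineup_size
        if int(k) != k or k < 2:
            raise ValidationError(f"lineup_size={k!r} must be an integer >= 2")

    def as_array(self) -> np.ndarray:
        return np.array([self.dP, self.b, self.g, self.dA], dtype=float)


@dataclass(frozen=True)
class ConditionSpec:
    """Design metadata for one experimental condition."""

    label: str
    lineup_format: str
    filler_type: str
    n_culprit_present: int
    n_culprit_absent: int

    def __post_init__(self) -> None:
        if self.lineup_format not in LINEUP_FORMATS:
            raise ValidationError(
                f"lineup_format={self.lineup_format!r} not in {LINEUP_FORMATS}"
            )
        if self.filler_type not in FILLER_TYPES:
            raise ValidationError(
                f"filler_type={self.filler_type!r} not in {FILLER_TYPES}"
            )
        for attr in ("n_culprit_present", "n_culprit_absent"):
            n = getattr(self, attr)
            if int(n) != n or n < 0:
                raise ValidationError(f"{attr}={n!r} must be a non-negative integer")


@dataclass(frozen=True)
class CategoryDistribution:
    """The six predicted response-category probabilities, three per tree."""

    cp_suspect: float
    cp_filler: float
    cp_reject: float
    ca_suspect: float
    ca_filler: float
    ca_reject: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12):
            raise ValidationError("category probabilities must be non-negative")
        for tree, total in (("culprit-present", arr[:3].sum()),
                            ("culprit-absent", arr[3:].sum())):
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{tree} tree probabilities sum to {total!r}, not 1"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in CATEGORY_ORDER], dtype=float)

    def cp(self) -> np.ndarray:
        return self.as_array()[:3]

    def ca(self) -> np.ndarray:
        return self.as_array()[3:]


@dataclass(frozen=True)
class ResponseTable:
    """Observed six-category counts for one condition."""

    condition: ConditionSpec
    cp_suspect: int
    cp_filler: int
    cp_reject: int
    ca_suspect: int
    ca_filler: int
    ca_reject: int

    def __post_init__(self) -> None:
        for cat in CATEGORY_ORDER:
            n = getattr(self, cat)
            if int(n) != n or n < 0:
                raise ValidationError(f"count {cat}={n!r} must be a non-negative integer")
        if self.cp_suspect + self.cp_filler + self.cp_reject != self.condition.n_culprit_present:
            raise ValidationError(
                f"condition {self.condition.label!r}: culprit-present counts sum to "
                f"{self.cp_suspect + self.cp_filler + self.cp_reject}, expected "
                f"{self.condition.n_culprit_present}"
            )
        if self.ca_suspect + self.ca_filler + self.ca_reject != self.condition.n_culprit_absent:
            raise ValidationError(
                f"condition {self.condition.label!r}: culprit-absent counts sum to "
                f"{self.ca_suspect + self.ca_filler + self.ca_reject}, expected "
                f"{self.condition.n_culprit_absent}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in CATEGORY_ORDER], dtype=float)

    @property
    def n_total(self) -> int:
        return self.condition.n_culprit_present + self.condition.n_culprit_absent

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_array(), index=list(CATEGORY_ORDER), name=self.condition.label)


def category_probability_array(theta: np.ndarray, lineup_size: np.ndarray | float) -> np.ndarray:
    """Vectorised category probabilities.

    Parameters
    ----------
    theta
        Array of shape ``(..., 4)`` holding ``(dP, b, g, dA)``.
    lineup_size
        Scalar or array broadcastable against ``theta[..., 0]``.

    Returns
    -------
    Array of shape ``(..., 6)`` in :data:`CATEGORY_ORDER`.
    """
    theta = np.asarray(theta, dtype=float)
    dP, b, g, dA = (theta[..., i] for i in range(4))
    invk = 1.0 / np.asarray(lineup_size, dtype=float)
    cp_s = dP + (1 - dP) * b + (1 - dP) * (1 - b) * g * invk
    cp_f = (1 - dP) * (1 - b) * g * (1 - invk)
    cp_r = (1 - dP) * (1 - b) * (1 - g)
    ca_s = (1 - dA) * b + (1 - dA) * (1 - b) * g * invk
    ca_f = (1 - dA) * (1 - b) * g * (1 - invk)
    ca_r = dA + (1 - dA) * (1 - b) * (1 - g)
    return np.stack([cp_s, cp_f, cp_r, ca_s, ca_f, ca_r], axis=-1)


def predict_category_probabilities(params: ModelParameters) -> CategoryDistribution:
    """Map latent-process parameters to the six response-category probabilities."""
    probs = category_probability_array(params.as_array(), params.lineup_size)
    return CategoryDistribution(*probs.tolist())


def expected_counts(params: ModelParameters, condition: ConditionSpec) -> pd.Series:
    """Expected category counts: tree probabilities times that tree's trial count."""
    probs = predict_category_probabilities(params).as_array()
    totals = np.array(
        [condition.n_culprit_present] * 3 + [condition.n_culprit_absent] * 3, dtype=float
    )
    return pd.Series(probs * totals, index=list(CATEGORY_ORDER), name=condition.label)


def read_response_tables(path: str | Path) -> list[ResponseTable]:
    """Read response tables from CSV (one condition per row).

    Columns: ``condition,lineup_format,filler_type,cp_suspect,cp_filler,
    cp_reject,ca_suspect,ca_filler,ca_reject``.  Tree totals are implied by
    the counts.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    tables = []
    for i, row in df.iterrows():
        try:
            cond = ConditionSpec(
                label=str(row["condition"]),
                lineup_format=str(row["lineup_format"]),
                filler_type=str(row["filler_type"]),
                n_culprit_present=int(row["cp_suspect"] + row["cp_filler"] + row["cp_reject"]),
                n_culprit_absent=int(row["ca_suspect"] + row["ca_filler"] + row["ca_reject"]),
            )
            tables.append(
                ResponseTable(cond, *(int(row[c]) for c in CATEGORY_ORDER))
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {i + 2}: {exc}") from exc
    labels = [t.condition.label for t in tables]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{path}: duplicate condition labels {labels}")
    return tables


def write_response_tables(tables: Iterable[ResponseTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        row = {
            "condition": t.condition.label,
            "lineup_format": t.condition.lineup_format,
            "filler_type": t.condition.filler_type,
        }
        row.update({c: getattr(t, c) for c in CATEGORY_ORDER})
        rows.append(row)
    pd.DataFrame(rows, columns=list(_CSV_COLUMNS)).to_csv(path, index=False)
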