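"""Lineup-fairness measures.

Mock-witness measures (Tredoux's E, proportion of suspect selections, the
pooled two-proportion z-test) operate on choice-count distributions over
lineup members.  Resultant measures apply the same mathematics to
culprit-absent eyewitness identifications (rejections excluded), and
identification rates summarise overall choosing from response tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ResponseTable, ValidationError

__all__ = [
    "ChoiceDistribution",
    "tredoux_e",
    "proportion_suspect",
    "two_proportion_z",
    "resultant_suspect_proportion",
    "resultant_tredoux_e",
    "identification_rate",
    "read_choice_distributions",
    "write_choice_distributions",
]


@dataclass(frozen=True)
class ChoiceDistribution:
    """Choice counts over the members of one lineup."""

    counts: tuple[int, ...]
    suspect_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.counts) < 2:
            raise ValidationError("a lineup needs at least two members")
        if any(c < 0 for c in self.counts):
            raise ValidationError(f"negative choice counts: {self.counts}")
        if not 0 <= self.suspect_index < len(self.counts):
            raise ValidationError(
                f"suspect_index={self.suspect_index} out of range for "
                f"{len(self.counts)} members"
            )

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValidationError("empty choice distribution")
        return np.asarray(self.counts, dtype=float) / self.total


def tredoux_e(dist: ChoiceDistribution) -> float:
    """Effective lineup size: E = 1 / sum of squared choice proportions.

    Ranges from 1 (all choices on one member) to k (uniform choices).
    """
    p = dist.proportions()
    return float(1.0 / np.sum(p**2))


def proportion_suspect(dist: ChoiceDistribution) -> float:
    """Share of choices falling on the suspect."""
    return float(dist.proportions()[dist.suspect_index])


def two_proportion_z(
    successes1: int, n1: int, successes2: int, n2: int
) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p)."""
    for s, n in ((successes1, n1), (successes2, n2)):
        if n <= 0:
            raise ValidationError(f"sample size {n!r} must be positive")
        if not 0 <= s <= n:
            raise ValidationError(f"successes {s!r} outside [0, {n}]")
    p1, p2 = successes1 / n1, successes2 / n2
    pooled = (successes1 + successes2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        import warnings

        warnings.warn("degenerate pooled proportion; z defined as 0")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = float((p1 - p2) / se)
    return z, float(2 * stats.norm.sf(abs(z)))


def resultant_suspect_proportion(table: ResponseTable) -> float:
    """Innocent-suspect identifications over all culprit-absent identifications."""
    denom = table.ca_suspect + table.ca_filler
    if denom == 0:
        raise ValidationError(
            f"condition {table.condition.label!r}: no culprit-absent identifications"
        )
    return table.ca_suspect / denom


def resultant_tredoux_e(dist: ChoiceDistribution) -> float:
    """Tredoux's E applied to culprit-absent eyewitness identifications.

    Identical mathematics to :func:`tredoux_e`; the distribution must be
    built from identifications only (lineup rejections excluded).
    """
    return tredoux_e(dist)


def identification_rate(tables: Sequence[ResponseTable]) -> float:
    """All identifications (suspect + filler, both trees) over all decisions."""
    if not tables:
        raise ValidationError("need at least one response table")
    picks = sum(t.cp_suspect + t.cp_filler + t.ca_suspect + t.ca_filler for t in tables)
    total = sum(t.n_total for t in tables)
    if total == 0:
        raise ValidationError("no decisions in the supplied tables")
    return picks / total


def read_choice_distributions(path: str | Path) -> dict[str, ChoiceDistribution]:
    """Read per-lineup choice counts from CSV.

    Columns: ``lineup_id,member_index,is_suspect,count``; exactly one member
    per lineup flagged as the suspect.
    """
    df = pd.read_csv(path)
    required = ["lineup_id", "member_index", "is_suspect", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    out: dict[str, ChoiceDistribution] = {}
    for lineup_id, grp in df.groupby("lineup_id", sort=False):
        grp = grp.sort_values("member_index")
        if list(grp["member_index"]) != list(range(len(grp))):
            raise ValidationError(
                f"{path}: lineup {lineup_id!r} member_index must be 0..k-1 without gaps"
            )
        suspects = grp.index[grp["is_suspect"].astype(bool)].tolist()
        if len(suspects) != 1:
            raise ValidationError(
                f"{path}: lineup {lineup_id!r} must flag exactly one suspect"
            )
        suspect_index = int(grp.loc[suspects[0], "member_index"])
        out[str(lineup_id)] = ChoiceDistribution(
            tuple(int(c) for c in grp["count"]), suspect_index
        )
    return out


def write_choice_distributions(
    dists: Mapping[str, ChoiceDistribution], path: str | Path
) -> None:
    rows = []
    for lineup_id, dist in dists.items():
        for i, c in enumerate(dist.counts):
            rows.append(
                {
                    "lineup_id": lineup_id,
                    "member_index": i,
                    "is_suspect": int(i == dist.suspect_index),
                    "count": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
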