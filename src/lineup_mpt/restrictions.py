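"""Equality restrictions across conditions.

A :class:`RestrictionSet` assigns every (condition, parameter) slot to a
named free-parameter group.  Slots in the same group share a single free
parameter during fitting; a group may instead be fixed to a constant.
Restriction sets are immutable: :meth:`share` and :meth:`fix` return new
objects, which makes building nested chains of models explicit and safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .model import PARAM_NAMES, ValidationError

__all__ = ["RestrictionSet", "load_restrictions"]

Slot = tuple[str, str]  # (condition label, parameter name)


def _group_name(param: str, members: Sequence[str], all_labels: Sequence[str]) -> str:
    if set(members) == set(all_labels):
        return f"{param}:all"
    ordered = [lab for lab in all_labels if lab in set(members)]
    return f"{param}:" + "+".join(ordered)


@dataclass(frozen=True)
class RestrictionSet:
    """Partition of (condition, parameter) slots into shared free parameters."""

    labels: tuple[str, ...]
    slot_groups: Mapping[Slot, str]
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.labels:
            for param in PARAM_NAMES:
                if (label, param) not in self.slot_groups:
                    raise ValidationError(f"slot ({label}, {param}) not covered")
        for slot in self.slot_groups:
            if slot[0] not in self.labels or slot[1] not in PARAM_NAMES:
                raise ValidationError(f"unknown slot {slot}")
        for group, value in self.fixed.items():
            if group not in set(self.slot_groups.values()):
                raise ValidationError(f"fixed group {group!r} does not exist")
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"fixed value {value!r} for {group!r} outside [0, 1]")

    # -- constructors ------------------------------------------------------

    @classmethod
    def free(cls, labels: Sequence[str]) -> "RestrictionSet":
        """Every slot its own free parameter (the unrestricted joint model)."""
        labels = tuple(labels)
        groups = {
            (lab, p): _group_name(p, [lab], labels) for lab in labels for p in PARAM_NAMES
        }
        return cls(labels, groups)

    def share(self, param: str, conditions: Sequence[str] | str) -> "RestrictionSet":
        """Return a new set in which ``param`` is equal across ``conditions``.

        ``conditions`` may be the string ``"all"``.  Groups already touching
        any of the named slots are merged transitively.
        """
        if param not in PARAM_NAMES:
            raise ValidationError(f"unknown parameter {param!r}")
        labs = self.labels if conditions == "all" else tuple(conditions)
        unknown = [lab for lab in labs if lab not in self.labels]
        if unknown:
            raise ValidationError(f"unknown condition labels {unknown}")
        if len(labs) < 2:
            raise ValidationError("share needs at least two conditions")
        touched = {self.slot_groups[(lab, param)] for lab in labs}
        members = [
            lab for lab in self.labels if self.slot_groups[(lab, param)] in touched
        ]
        new_name = _group_name(param, members, self.labels)
        fixed_hits = {g: v for g, v in self.fixed.items() if g in touched}
        if len(set(fixed_hits.values())) > 1:
            raise ValidationError(
                f"cannot merge groups fixed to different values: {fixed_hits}"
            )
        groups = dict(self.slot_groups)
        for lab in members:
            groups[(lab, param)] = new_name
        fixed = {g: v for g, v in self.fixed.items() if g not in touched}
        if fixed_hits:
            fixed[new_name] = next(iter(fixed_hits.values()))
        return RestrictionSet(self.labels, groups, fixed)

    def fix(self, param: str, conditions: Sequence[str] | str, value: float) -> "RestrictionSet":
        """Return a new set with ``param`` fixed to ``value`` in ``conditions``."""
        rs = self if (conditions != "all" and len(tuple(conditions)) == 1) else self.share(param, conditions)
        labs = rs.labels if conditions == "all" else tuple(conditions)
        group = rs.slot_groups[(labs[0], param)]
        fixed = dict(rs.fixed)
        fixed[group] = float(value)
        return RestrictionSet(rs.labels, rs.slot_groups, fixed)

    # -- queries -----------------------------------------------------------

    def group_of(self, label: str, param: str) -> str:
        return self.slot_groups[(label, param)]

    @property
    def group_names(self) -> tuple[str, ...]:
        """All group names, ordered by first slot appearance (labels x params)."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            for p in PARAM_NAMES:
                seen.setdefault(self.slot_groups[(lab, p)], None)
        return tuple(seen)

    @property
    def free_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.group_names if g not in self.fixed)

    @property
    def n_free(self) -> int:
        return len(self.free_groups)

    def members(self, group: str) -> tuple[Slot, ...]:
        return tuple(s for s, g in self.slot_groups.items() if g == group)

    def refines(self, other: "RestrictionSet") -> bool:
        """True if this set is at least as restrictive as ``other``.

        Every pair of slots shared under ``other`` must also be shared here,
        and every constant fixed under ``other`` must be fixed to the same
        value here.  A model whose restriction set strictly refines another's
        is nested within it.
        """
        if set(self.labels) != set(other.labels):
            return False
        rep: dict[str, Slot] = {}
        for slot, g in other.slot_groups.items():
            if g in rep:
                if self.slot_groups[slot] != self.slot_groups[rep[g]]:
                    return False
            else:
                rep[g] = slot
        for g, v in other.fixed.items():
            slot = rep[g]
            mine = self.slot_groups[slot]
            if self.fixed.get(mine) != v:
                return False
        return True

    def describe(self) -> str:
        lines = []
        for g in self.group_names:
            slots = ", ".join(f"{lab}.{p}" for lab, p in self.members(g))
            tail = f" = {self.fixed[g]}" if g in self.fixed else ""
            lines.append(f"{g}: {slots}{tail}")
        return "\n".join(lines)

    # -- config ------------------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping, labels: Sequence[str]) -> "RestrictionSet":
        """Build from the declarative schema::

            share:
              - {param: dA, conditions: all}
              - {param: dP, conditions: [sim_morphed, sim_nonmorphed]}
            fix:
              - {param: g, conditions: [seq_morphed], value: 0.5}
        """
        rs = cls.free(labels)
        for entry in config.get("share", []) or []:
            rs = rs.share(entry["param"], entry["conditions"])
        for entry in config.get("fix", []) or []:
            rs = rs.fix(entry["param"], entry["conditions"], entry["value"])
        return rs


def load_restrictions(path: str | Path, labels: Sequence[str]) -> RestrictionSet:
    """Load a restriction config from a YAML (or JSON, a YAML subset) file."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, Mapping):
        raise ValidationError(f"{path}: restriction config must be a mapping")
    return RestrictionSet.from_config(config, labels)
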