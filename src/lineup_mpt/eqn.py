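"""Export/import of the model in the de facto MPT equation-file dialect.

Each line after the header is ``<tree> <category> <branch term>`` where the
branch term is a ``*``-separated product of parameter names, complements
written as ``(1-name)``.  Branches reaching the same category are summed.
The header line holds the number of branch lines.

The ``1/k`` guessing split has no free parameter of its own: it is written
as the pseudo-parameter ``u`` (``(1-u)`` for the filler side), which must be
bound to ``1/lineup_size`` when the file is used elsewhere.  With that
binding, one condition serialises to 10 branch lines: 5 culprit-present and
5 culprit-absent tree paths, collapsing to 3 categories each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import PARAM_NAMES, ValidationError
from .restrictions import RestrictionSet

__all__ = ["EqnModel", "serialize_eqn", "parse_eqn", "GUESS_SPLIT_NAME"]

#: Pseudo-parameter carrying the 1/k guessing split.
GUESS_SPLIT_NAME = "u"

Factor = tuple[str, bool]  # (parameter name, complemented?)
Branch = tuple[int, tuple[Factor, ...]]  # (category index, product term)


@dataclass(frozen=True)
class EqnModel:
    """Parsed equation file: branches grouped by tree index."""

    trees: tuple[tuple[int, tuple[Branch, ...]], ...]

    def parameters(self) -> set[str]:
        return {
            name
            for _, branches in self.trees
            for _, factors in branches
            for name, _ in factors
        }

    def evaluate(self, values: Mapping[str, float]) -> dict[int, dict[int, float]]:
        """Category probabilities per tree by summing branch products."""
        out: dict[int, dict[int, float]] = {}
        for tree, branches in self.trees:
            cats: dict[int, float] = {}
            for category, factors in branches:
                prod = 1.0
                for name, complemented in factors:
                    v = values[name]
                    prod *= (1.0 - v) if complemented else v
                cats[category] = cats.get(category, 0.0) + prod
            out[tree] = cats
        return out


def _slot_names(
    labels: Sequence[str], restrictions: RestrictionSet | None
) -> dict[tuple[str, str], str]:
    names = {}
    for lab in labels:
        for p in PARAM_NAMES:
            if restrictions is None:
                names[(lab, p)] = f"{p}_{lab}"
            else:
                group = restrictions.group_of(lab, p)
                names[(lab, p)] = group.replace(":", "_").replace("+", "_")
    return names


def serialize_eqn(
    labels: Sequence[str], restrictions: RestrictionSet | None = None
) -> str:
    """Serialise the two-tree model for the given conditions.

    Trees are numbered consecutively: condition ``i`` (0-based) owns trees
    ``2i+1`` (culprit-present) and ``2i+2`` (culprit-absent); categories are
    numbered globally, three per tree.  Shared parameters get one name per
    group when ``restrictions`` is given.
    """
    if not labels:
        raise ValidationError("need at least one condition label")
    names = _slot_names(labels, restrictions)
    u = GUESS_SPLIT_NAME
    lines: list[str] = []
    for i, lab in enumerate(labels):
        dP, b, g, dA = (names[(lab, p)] for p in PARAM_NAMES)
        cp_tree, ca_tree = 2 * i + 1, 2 * i + 2
        cp_cat = 3 * (cp_tree - 1)  # categories cp_cat+1..cp_cat+3
        ca_cat = 3 * (ca_tree - 1)
        lines += [
            f"{cp_tree} {cp_cat + 1} {dP}",
            f"{cp_tree} {cp_cat + 1} (1-{dP})*{b}",
            f"{cp_tree} {cp_cat + 1} (1-{dP})*(1-{b})*{g}*{u}",
            f"{cp_tree} {cp_cat + 2} (1-{dP})*(1-{b})*{g}*(1-{u})",
            f"{cp_tree} {cp_cat + 3} (1-{dP})*(1-{b})*(1-{g})",
            f"{ca_tree} {ca_cat + 1} (1-{dA})*{b}",
            f"{ca_tree} {ca_cat + 1} (1-{dA})*(1-{b})*{g}*{u}",
            f"{ca_tree} {ca_cat + 2} (1-{dA})*(1-{b})*{g}*(1-{u})",
            f"{ca_tree} {ca_cat + 3} (1-{dA})*(1-{b})*(1-{g})",
            f"{ca_tree} {ca_cat + 3} {dA}",
        ]
    return "\n".join([str(len(lines))] + lines) + "\n"


def _parse_factor(token: str) -> Factor:
    token = token.strip()
    if token.startswith("(") and token.endswith(")"):
        inner = token[1:-1].strip()
        if not inner.startswith("1-"):
            raise ValidationError(f"cannot parse factor {token!r}")
        return inner[2:].strip(), True
    if not token or any(ch in token for ch in "()*"):
        raise ValidationError(f"cannot parse factor {token!r}")
    return token, False


def parse_eqn(text: str) -> EqnModel:
    """Parse equation-file text back into a branch structure.

    The first line (branch count or comment) is validated when numeric and
    otherwise skipped, per the common dialect options.
    """
    raw = [line.strip() for line in text.splitlines()]
    raw = [line for line in raw if line and not line.startswith("#")]
    if not raw:
        raise ValidationError("empty equation file")
    body = raw
    header = raw[0].split()
    if len(header) == 1:
        try:
            declared = int(header[0])
        except ValueError:
            body = raw[1:]
        else:
            body = raw[1:]
            if declared != len(body):
                raise ValidationError(
                    f"header declares {declared} branch lines, found {len(body)}"
                )
    trees: dict[int, list[Branch]] = {}
    for lineno, line in enumerate(body, start=2):
        parts = line.split(None, 2)
        if len(parts) != 3:
            raise ValidationError(f"line {lineno}: expected 'tree category term', got {line!r}")
        try:
            tree, category = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: non-integer tree/category in {line!r}") from exc
        factors = tuple(_parse_factor(tok) for tok in parts[2].split("*"))
        trees.setdefault(tree, []).append((category, factors))
    return EqnModel(tuple((t, tuple(branches)) for t, branches in sorted(trees.items())))
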