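"""Bundled datasets and canonical restriction configurations.

The three eyewitness datasets (``exp2``, ``exp3``, ``exp4``) are the
published six-category response-frequency tables for four conditions each:
simultaneous/sequential lineup format crossed with morphed/non-morphed
fillers.  Counts are the sufficient statistics; proportions are derived and
not stored.  Every table is validated at load time against its per-tree
total (participants x 2 decisions per tree), so a transcription error fails
loudly.

``REFERENCE`` holds the published headline statistics for the bundled
datasets, used by the ``reproduce`` command for side-by-side display only —
never as a substitute for computation.
"""

from __future__ import annotations

from .model import ConditionSpec, ResponseTable, ValidationError
from .restrictions import RestrictionSet

__all__ = [
    "CONDITION_LABELS",
    "load_fixture",
    "available_fixtures",
    "base_restrictions",
    "participants",
    "REFERENCE",
    "EXP1_SUSPECT_CHOICES",
]

CONDITION_LABELS = ("sim_morphed", "sim_nonmorphed", "seq_morphed", "seq_nonmorphed")

_FORMATS = {
    "sim_morphed": ("simultaneous", "morphed"),
    "sim_nonmorphed": ("simultaneous", "non-morphed"),
    "seq_morphed": ("sequential", "morphed"),
    "seq_nonmorphed": ("sequential", "non-morphed"),
}

# label -> (participants, (cp_suspect, cp_filler, cp_reject), (ca_suspect, ca_filler, ca_reject))
_DATA = {
    "exp2": {
        "sim_morphed": (199, (177, 120, 101), (93, 161, 144)),
        "sim_nonmorphed": (190, (155, 117, 108), (66, 160, 154)),
        "seq_morphed": (196, (112, 220, 60), (58, 247, 87)),
        "seq_nonmorphed": (198, (130, 201, 65), (67, 234, 95)),
    },
    "exp3": {
        "sim_morphed": (197, (154, 117, 123), (70, 131, 193)),
        "sim_nonmorphed": (180, (132, 95, 133), (47, 135, 178)),
        "seq_morphed": (195, (116, 208, 66), (53, 235, 102)),
        "seq_nonmorphed": (188, (126, 184, 66), (58, 220, 98)),
    },
    "exp4": {
        "sim_morphed": (183, (135, 86, 145), (49, 119, 198)),
        "sim_nonmorphed": (200, (144, 119, 137), (55, 139, 206)),
        "seq_morphed": (194, (125, 189, 74), (69, 209, 110)),
        "seq_nonmorphed": (184, (126, 163, 79), (62, 199, 107)),
    },
}

# Mock-witness suspect-selection counts reconstructed from the published
# proportions (47.5% of 385x4 choices, 25.0% of 368x4 choices).  0.475*1540
# is exactly 731.5; 732 is used, and either adjacent integer reproduces the
# published z to one decimal.
EXP1_SUSPECT_CHOICES = {"morphed": (732, 1540), "nonmorphed": (368, 1472)}

#: Published statistics for side-by-side display in ``reproduce``.
REFERENCE = {
    "exp2": {
        "G2": (2.55, 7, 0.924),
        "tests": {
            "b: sim_morphed = sim_nonmorphed": (5.31, 0.021, 0.04),
            "b: seq_morphed = seq_nonmorphed": (2.04, 0.153, 0.03),
            "b: sim_morphed = seq_morphed": (21.89, 0.001, 0.08),
            "b: sim_nonmorphed = seq_nonmorphed": (1.60, 0.207, 0.02),
            "dP: simultaneous = sequential": (8.25, 0.004, 0.05),
        },
        "estimates": {
            ("dP", "sim_morphed"): (0.27, 0.03),
            ("g", "sim_morphed"): (0.59, 0.02),
            ("dA", "sim_morphed"): (0.04, 0.02),
            ("dP", "seq_morphed"): (0.17, 0.02),
            ("g", "seq_morphed"): (0.80, 0.02),
        },
    },
    "exp3": {
        "G2": (3.58, 7, 0.827),
        "tests": {
            "b: sim_morphed = sim_nonmorphed": (3.63, 0.057, 0.03),
            "b: seq_morphed = seq_nonmorphed": (1.49, 0.222, 0.02),
            "b: sim_morphed = seq_morphed": (12.53, 0.001, 0.06),
            "b: sim_nonmorphed = seq_nonmorphed": (0.42, 0.515, 0.01),
            "dP: simultaneous = sequential": (3.78, 0.052, 0.04),
        },
        "estimates": {
            ("dP", "sim_morphed"): (0.26, 0.02),
            ("g", "sim_morphed"): (0.50, 0.02),
            ("dA", "sim_morphed"): (0.06, 0.03),
            ("dP", "seq_morphed"): (0.19, 0.02),
            ("g", "seq_morphed"): (0.78, 0.02),
        },
    },
    "exp4": {
        "G2": (6.61, 7, 0.471),
        "tests": {
            "b: sim_morphed = sim_nonmorphed": (0.01, 0.992, 0.01),
            "b: seq_morphed = seq_nonmorphed": (0.01, 0.950, 0.01),
            "b: sim_morphed = seq_morphed": (0.02, 0.898, 0.01),
            "b: sim_nonmorphed = seq_nonmorphed": (0.01, 0.952, 0.01),
            "dP: simultaneous = sequential": (4.80, 0.028, 0.04),
        },
        "estimates": {
            ("dP", "sim_morphed"): (0.26, 0.02),
            ("g", "sim_morphed"): (0.46, 0.02),
            ("dA", "sim_morphed"): (0.06, 0.03),
            ("dP", "seq_morphed"): (0.18, 0.03),
            ("g", "seq_morphed"): (0.74, 0.02),
        },
    },
}


def available_fixtures() -> tuple[str, ...]:
    return tuple(sorted(_DATA))


def participants(name: str, label: str) -> int:
    return _DATA[name][label][0]


def load_fixture(name: str) -> list[ResponseTable]:
    """Return the four validated response tables of a bundled dataset."""
    if name not in _DATA:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    tables = []
    for label in CONDITION_LABELS:
        n, cp, ca = _DATA[name][label]
        fmt, filler = _FORMATS[label]
        # two culprit-present and two culprit-absent decisions per participant
        cond = ConditionSpec(label, fmt, filler, 2 * n, 2 * n)
        tables.append(ResponseTable(cond, *cp, *ca))
    return tables


def base_restrictions(labels: tuple[str, ...] = CONDITION_LABELS) -> RestrictionSet:
    """The canonical base model: ``dA`` equal across all four conditions,
    ``dP`` and ``g`` equal within lineup format, ``b`` free per condition."""
    return (
        RestrictionSet.free(labels)
        .share("dA", "all")
        .share("dP", ["sim_morphed", "sim_nonmorphed"])
        .share("dP", ["seq_morphed", "seq_nonmorphed"])
        .share("g", ["sim_morphed", "sim_nonmorphed"])
        .share("g", ["seq_morphed", "seq_nonmorphed"])
    )
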