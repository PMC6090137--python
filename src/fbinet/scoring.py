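"""Interaction-strength grading of day-3/5/7 significance patterns.

The signed significance calls at the three observation days form an
ordered triplet over {-1, 0, +1}. Monotone patterns (all non-negative or
all non-positive) are graded by a fixed lookup to a signed strength in
[-6, +6]: persistent significance from day 3 is the strongest class
("strong induction", +6), later onsets grade lower, and transient
early-only significance grades lowest ("acceleration", +1..+3). The
lookup is exactly that — not a weighted sum of days: (0,0,1) and (1,0,1)
both grade 4, which no per-day weighting reproduces.

Patterns mixing +1 and -1 across days fall outside the monotone
taxonomy; they are graded 0 and flagged ``mixed`` rather than assigned a
net direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

Pattern = tuple[int, int, int]

# Positive half of the lookup; negatives follow by antisymmetry.
_POSITIVE_GRADES: dict[Pattern, tuple[int, str]] = {
    (1, 1, 1): (6, "strong induction"),
    (0, 1, 1): (5, "induction"),
    (0, 0, 1): (4, "mild induction"),
    (1, 0, 1): (4, "mild induction"),
    (1, 1, 0): (3, "acceleration"),
    (0, 1, 0): (2, "acceleration"),
    (1, 0, 0): (1, "acceleration"),
}

_NEGATIVE_LABEL = {
    "strong induction": "strong inhibition",
    "induction": "inhibition",
    "mild induction": "mild inhibition",
    "acceleration": "retardation",
}

#: Full pattern -> (grade, label) table: 14 graded rows plus the null row.
GRADE_TABLE: dict[Pattern, tuple[int, str]] = {(0, 0, 0): (0, "none")}
for _pat, (_val, _label) in _POSITIVE_GRADES.items():
    GRADE_TABLE[_pat] = (_val, _label)
    GRADE_TABLE[tuple(-e for e in _pat)] = (-_val, _NEGATIVE_LABEL[_label])


@dataclass(frozen=True)
class InteractionGrade:
    """Signed interaction strength with its class label."""

    value: int
    label: str
    mixed: bool = False


def grade_pattern(pattern: Sequence[int]) -> InteractionGrade:
    """Grade one day-3/5/7 significance pattern.

    Exact lookup of the 14 monotone rows; (0,0,0) grades 0 ("none");
    any pattern containing both +1 and -1 grades 0 with the ``mixed``
    flag set. Entries outside {-1, 0, +1} are rejected.
    """
    pat = tuple(int(e) for e in pattern)
    if len(pat) != 3 or any(e not in (-1, 0, 1) for e in pat):
        raise ValueError(f"pattern must be three entries in {{-1,0,1}}, got {pattern!r}")
    if 1 in pat and -1 in pat:
        return InteractionGrade(0, "mixed", mixed=True)
    value, label = GRADE_TABLE[pat]
    return InteractionGrade(value, label)


GRADES_COLUMNS = [
    "focal",
    "kingdom",
    "partner",
    "medium",
    "d3",
    "d5",
    "d7",
    "grade",
    "label",
    "flags",
]


def grade_all(
    comparisons: pd.DataFrame,
    days: Sequence[int] = (3, 5, 7),
) -> pd.DataFrame:
    """Grade every (focal, partner, medium) from its per-day comparisons.

    Each key must contribute exactly one comparison per configured day;
    duplicate days are rejected, keys missing a day are reported with
    ``flags='incomplete'`` and no grade. Comparisons flagged
    ``missing_control`` count as missing days.
    """
    days = list(days)
    day_cols = [f"d{d}" for d in days]
    usable = comparisons[comparisons["status"] != "missing_control"]

    rows = []
    for (focal, kingdom, partner, medium), grp in usable.groupby(
        ["focal", "kingdom", "partner", "medium"], sort=True
    ):
        if grp["day"].duplicated().any():
            raise ValueError(
                f"duplicate day for ({focal}, {partner}, {medium})"
            )
        calls = dict(zip(grp["day"], grp["sign_call"]))
        row = {
            "focal": focal,
            "kingdom": kingdom,
            "partner": partner,
            "medium": medium,
        }
        if set(days) - set(calls):
            row.update({c: pd.NA for c in day_cols})
            row.update(grade=pd.NA, label="", flags="incomplete")
        else:
            pattern = tuple(int(calls[d]) for d in days)
            g = grade_pattern(pattern)
            row.update(dict(zip(day_cols, pattern)))
            row.update(grade=g.value, label=g.label, flags="mixed" if g.mixed else "")
        rows.append(row)

    # keys that only ever appeared with a missing control
    dropped = comparisons[comparisons["status"] == "missing_control"]
    seen = {tuple(r[k] for k in ("focal", "kingdom", "partner", "medium")) for r in rows}
    for key, _ in dropped.groupby(["focal", "kingdom", "partner", "medium"], sort=True):
        if key not in seen:
            row = dict(zip(("focal", "kingdom", "partner", "medium"), key))
            row.update({c: pd.NA for c in day_cols})
            row.update(grade=pd.NA, label="", flags="incomplete")
            rows.append(row)

    return pd.DataFrame(rows, columns=GRADES_COLUMNS)
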