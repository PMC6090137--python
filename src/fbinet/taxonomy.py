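"""Identity-threshold taxonomic rank assignment for sequence hits.

Implements the banding rule used to turn BLAST-style hit summaries into
a taxonomic rank: hits covering less than 94% of the query are ignored,
and the percent identity of the remaining hits is banded into presumed
species (98-100%), genus (94-97%) or order (80-93%). Conflicting hits
are resolved to the lowest (least specific) common rank. Fractional
identities falling between the printed integer bands are resolved by
half-open intervals [94, 98) and [80, 94), which make the map total.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

SPECIES = "species"
GENUS = "genus"
ORDER = "order"
UNASSIGNED = "unassigned"

#: Specificity ordering; lower is less specific.
_SPECIFICITY = {UNASSIGNED: 0, ORDER: 1, GENUS: 2, SPECIES: 3}

MIN_COVERAGE_PCT = 94.0


def assign_rank(identity_pct: float, coverage_pct: float) -> str:
    """Band one hit's identity into a rank, gated on query coverage."""
    if not (0 <= identity_pct <= 100) or not (0 <= coverage_pct <= 100):
        raise ValueError("identity and coverage must lie in [0, 100]")
    if coverage_pct < MIN_COVERAGE_PCT:
        return UNASSIGNED
    if identity_pct >= 98.0:
        return SPECIES
    if identity_pct >= 94.0:
        return GENUS
    if identity_pct >= 80.0:
        return ORDER
    return UNASSIGNED


def lowest_common_rank(ranks: Sequence[str]) -> str:
    """Least specific rank present (conflicting-hits rule).

    ``unassigned`` dominates everything; order < genus < species.
    Idempotent and order-independent.
    """
    if len(ranks) == 0:
        raise ValueError("lowest_common_rank needs at least one rank")
    unknown = [r for r in ranks if r not in _SPECIFICITY]
    if unknown:
        raise ValueError(f"unknown ranks: {unknown}")
    return min(ranks, key=_SPECIFICITY.__getitem__)


def assign_ranks_table(hits: pd.DataFrame) -> pd.DataFrame:
    """Vector version over a hit table.

    Expects columns ``hit_id, identity_pct, coverage_pct``; returns the
    table with a ``rank`` column appended.
    """
    required = ["hit_id", "identity_pct", "coverage_pct"]
    missing = [c for c in required if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    out = hits.copy()
    out["rank"] = [
        assign_rank(i, c) for i, c in zip(out["identity_pct"], out["coverage_pct"])
    ]
    return out


def consensus_rank(hits: pd.DataFrame) -> str:
    """Rank for one query from all its hits (band, then lowest common)."""
    return lowest_common_rank(list(assign_ranks_table(hits)["rank"]))
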