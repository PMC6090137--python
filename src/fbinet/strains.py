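"""Strain roster and experimental design constants.

The default roster mirrors a 4-fungus / 5-bacterium co-culture screen:
four fungal isolates (two *Coprinellus micaceus* strains, a
*Cladosporium* sp. and *Aspergillus niger*) crossed against five
bacterial isolates (four *Aeromonas* spp. and a *Vibrio* sp.) on four
agar media spanning a nutrient gradient, photographed at days 3, 5 and 7.
"""

from __future__ import annotations

from dataclasses import dataclass

FUNGUS = "fungus"
BACTERIUM = "bacterium"

#: Media labels ordered from intermediate to rich to poor as conventionally
#: tabulated: CP (carbohydrates + amino peptides), LB (amino peptides),
#: MM (low-nutrient marine medium), PDA (carbohydrates).
DEFAULT_MEDIA: tuple[str, ...] = ("CP", "LB", "MM", "PDA")

#: Observation days (photographs at 72 h, 120 h and 168 h).
DEFAULT_DAYS: tuple[int, ...] = (3, 5, 7)


@dataclass(frozen=True, order=True)
class StrainId:
    """A named strain with a fixed kingdom.

    ``name`` must be unique within a dataset; ``kingdom`` is either
    ``"fungus"`` or ``"bacterium"``.
    """

    name: str
    kingdom: str

    def __post_init__(self) -> None:
        if self.kingdom not in (FUNGUS, BACTERIUM):
            raise ValueError(f"unknown kingdom {self.kingdom!r}")


DEFAULT_FUNGI: tuple[StrainId, ...] = tuple(
    StrainId(name, FUNGUS) for name in ("F1", "F2", "F3", "F4")
)
DEFAULT_BACTERIA: tuple[StrainId, ...] = tuple(
    StrainId(name, BACTERIUM) for name in ("B1", "B2", "B3", "B4", "B5")
)
DEFAULT_ROSTER: tuple[StrainId, ...] = DEFAULT_FUNGI + DEFAULT_BACTERIA


def kingdoms_of(strains) -> dict[str, str]:
    """Map strain name -> kingdom, rejecting duplicate names."""
    out: dict[str, str] = {}
    for s in strains:
        if s.name in out:
            raise ValueError(f"duplicate strain name {s.name!r}")
        out[s.name] = s.kingdom
    return out


def cross_kingdom_pairs(strains) -> list[tuple[StrainId, StrainId]]:
    """Ordered (focal, partner) pairs with focal and partner in different
    kingdoms, in roster order. For the default 4+5 roster this yields 40
    ordered pairs (20 unordered pairs in two focal roles)."""
    return [
        (a, b)
        for a in strains
        for b in strains
        if a.kingdom != b.kingdom
    ]
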