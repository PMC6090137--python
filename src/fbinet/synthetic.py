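"""Synthetic colony-area generator.

Emulates the long-format table produced by image analysis of co-culture
plate photographs: one colony area per organism x medium x day x
replicate x culture condition (monoculture control or a named
cross-kingdom partner). Planted induction/repression effects are step
functions of day, so a planted effect with onset day 3/5/7 produces the
significance patterns (1,1,1)/(0,1,1)/(0,0,1) that the downstream
grading taxonomy is built around. Replicate noise is multiplicative
lognormal with a configurable coefficient of variation: areas are
positive and right-skewed, and the noise factor has mean exactly 1 so
sample means recover the planted expectations.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .strains import (
    BACTERIUM,
    DEFAULT_DAYS,
    DEFAULT_MEDIA,
    DEFAULT_ROSTER,
    FUNGUS,
    StrainId,
    cross_kingdom_pairs,
    kingdoms_of,
)

AREA_COLUMNS = ["focal", "kingdom", "partner", "medium", "day", "replicate", "area"]

# Default monoculture area trajectories (mm^2), linear in day. Placeholders
# with plausible plate-scale magnitudes: mycelial colonies outgrow bacterial
# ones on a 90 mm dish.
_DEFAULT_SLOPE = {FUNGUS: 150.0, BACTERIUM: 40.0}


@dataclass(frozen=True)
class EffectSpec:
    """A planted effect of ``partner`` on the growth of ``focal``.

    ``magnitude`` is the fractional change in expected colony area
    relative to the monoculture baseline (+0.5 = 50% larger), applied
    from ``onset_day`` onward. ``onset_day=None`` means no effect.
    Effects are direction-specific: an effect on ``focal`` implies
    nothing about the reverse direction.
    """

    focal: StrainId
    partner: StrainId
    medium: str
    onset_day: int | None
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.focal.kingdom == self.partner.kingdom:
            raise ValueError(
                f"effect {self.focal.name}<-{self.partner.name}: focal and "
                "partner must belong to different kingdoms"
            )
        if self.onset_day is not None and self.magnitude <= -1:
            raise ValueError("magnitude must be > -1 (areas stay positive)")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.focal.name, self.partner.name, self.medium)


def default_baselines(
    strains: Sequence[StrainId] = DEFAULT_ROSTER,
    days: Sequence[int] = DEFAULT_DAYS,
) -> dict[str, dict[int, float]]:
    """Per-strain expected monoculture area at each day (linear in day)."""
    return {
        s.name: {d: _DEFAULT_SLOPE[s.kingdom] * d for d in days} for s in strains
    }


@dataclass
class GeneratorConfig:
    """Full description of one simulated bioassay.

    Parameters
    ----------
    strains : roster of StrainId (names unique, kingdoms fixed).
    media : medium labels.
    days : ordered observation days.
    n_replicates : replicates per condition (>= 2).
    baseline_area : strain name -> day -> expected monoculture area;
        strictly positive, non-decreasing over days.
    noise_cv : coefficient of variation of the multiplicative replicate
        noise (0 = deterministic).
    effects : planted EffectSpec list; at most one per
        (focal, partner, medium).
    seed : RNG seed; identical config + seed gives identical output.
    """

    strains: Sequence[StrainId] = DEFAULT_ROSTER
    media: Sequence[str] = DEFAULT_MEDIA
    days: Sequence[int] = DEFAULT_DAYS
    n_replicates: int = 3
    baseline_area: Mapping[str, Mapping[int, float]] | None = None
    noise_cv: float = 0.1
    effects: Sequence[EffectSpec] = field(default_factory=tuple)
    seed: int | None = None

    def validate(self) -> None:
        kingdoms_of(self.strains)  # raises on duplicate names
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        base = self.resolved_baselines()
        for s in self.strains:
            if s.name not in base:
                raise ValueError(f"no baseline areas for strain {s.name!r}")
            prev = 0.0
            for d in self.days:
                a = base[s.name][d]
                if a <= 0:
                    raise ValueError(f"baseline area for {s.name} day {d} not positive")
                if a < prev:
                    raise ValueError(f"baseline areas for {s.name} decrease over days")
                prev = a
        seen: set[tuple[str, str, str]] = set()
        names = {s.name for s in self.strains}
        for e in self.effects:
            if e.focal.name not in names or e.partner.name not in names:
                raise ValueError(f"effect references strain outside roster: {e.key}")
            if e.medium not in self.media:
                raise ValueError(f"effect references unknown medium {e.medium!r}")
            if e.onset_day is not None and e.onset_day not in self.days:
                raise ValueError(f"effect onset day {e.onset_day} not a configured day")
            if e.key in seen:
                raise ValueError(f"duplicate effect for {e.key}")
            seen.add(e.key)

    def resolved_baselines(self) -> Mapping[str, Mapping[int, float]]:
        if self.baseline_area is None:
            return default_baselines(self.strains, self.days)
        return self.baseline_area

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "strains": [{"name": s.name, "kingdom": s.kingdom} for s in self.strains],
            "media": list(self.media),
            "days": list(self.days),
            "n_replicates": self.n_replicates,
            "baseline_area": {
                n: {int(d): float(a) for d, a in per.items()}
                for n, per in self.resolved_baselines().items()
            },
            "noise_cv": self.noise_cv,
            "effects": [
                {
                    "focal": e.focal.name,
                    "partner": e.partner.name,
                    "medium": e.medium,
                    "onset_day": e.onset_day,
                    "magnitude": e.magnitude,
                }
                for e in self.effects
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        strains = tuple(StrainId(s["name"], s["kingdom"]) for s in d["strains"])
        by_name = {s.name: s for s in strains}
        effects = tuple(
            EffectSpec(
                focal=by_name[e["focal"]],
                partner=by_name[e["partner"]],
                medium=e["medium"],
                onset_day=e["onset_day"],
                magnitude=e.get("magnitude", 0.0),
            )
            for e in d.get("effects", [])
        )
        baseline = d.get("baseline_area")
        if baseline is not None:
            baseline = {n: {int(k): float(v) for k, v in per.items()} for n, per in baseline.items()}
        return cls(
            strains=strains,
            media=tuple(d["media"]),
            days=tuple(d["days"]),
            n_replicates=d["n_replicates"],
            baseline_area=baseline,
            noise_cv=d["noise_cv"],
            effects=effects,
            seed=d.get("seed"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _expected_area(
    baseline: float,
    day: int,
    effect: EffectSpec | None,
) -> float:
    if effect is not None and effect.onset_day is not None and day >= effect.onset_day:
        return baseline * (1.0 + effect.magnitude)
    return baseline


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the long-format colony-area table for ``config``.

    One monoculture record per strain x medium x day x replicate, and one
    co-culture record per ordered cross-kingdom (focal, partner) pair x
    medium x day x replicate. The expected co-culture area is
    ``baseline * (1 + magnitude)`` for days at or after the onset of a
    matching planted effect, and the baseline otherwise. Replicate noise
    is mean-one multiplicative lognormal with CV ``config.noise_cv``.

    Returns a DataFrame with columns
    ``focal, kingdom, partner, medium, day, replicate, area``
    (``partner`` empty string for monoculture controls).
    """
    config.validate()
    base = config.resolved_baselines()
    effect_map = {e.key: e for e in config.effects}

    focal_l: list[str] = []
    kingdom_l: list[str] = []
    partner_l: list[str] = []
    medium_l: list[str] = []
    day_l: list[int] = []
    rep_l: list[int] = []
    expected: list[float] = []

    pairs = cross_kingdom_pairs(config.strains)
    for medium in config.media:
        for day in config.days:
            for rep in range(1, config.n_replicates + 1):
                for s in config.strains:
                    focal_l.append(s.name)
                    kingdom_l.append(s.kingdom)
                    partner_l.append("")
                    medium_l.append(medium)
                    day_l.append(day)
                    rep_l.append(rep)
                    expected.append(base[s.name][day])
                for focal, partner in pairs:
                    eff = effect_map.get((focal.name, partner.name, medium))
                    focal_l.append(focal.name)
                    kingdom_l.append(focal.kingdom)
                    partner_l.append(partner.name)
                    medium_l.append(medium)
                    day_l.append(day)
                    rep_l.append(rep)
                    expected.append(_expected_area(base[focal.name][day], day, eff))

    mu = np.asarray(expected, dtype=float)
    rng = np.random.default_rng(config.seed)
    if config.noise_cv > 0:
        # mean-one lognormal: sigma^2 = ln(1 + cv^2), location -sigma^2/2
        sigma2 = math.log1p(config.noise_cv**2)
        noise = np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size=mu.size))
    else:
        noise = np.ones_like(mu)
    area = mu * noise

    return pd.DataFrame(
        {
            "focal": focal_l,
            "kingdom": kingdom_l,
            "partner": partner_l,
            "medium": medium_l,
            "day": day_l,
            "replicate": rep_l,
            "area": area,
        }
    )


# -- canned study designs ----------------------------------------------


def null_config(seed: int | None = None, noise_cv: float = 0.1) -> GeneratorConfig:
    """Default roster with no planted effects (pure replicate noise)."""
    return GeneratorConfig(noise_cv=noise_cv, seed=seed)


def stress_gradient_config(
    seed: int | None = None,
    induction: float = 0.5,
    repression: float = -0.5,
    noise_cv: float = 0.1,
    onset_day: int = 3,
    induction_medium: str = "MM",
    repression_medium: str = "PDA",
) -> GeneratorConfig:
    """Planted stress-gradient scenario.

    Every cross-kingdom interaction in the low-nutrient medium is an
    induction (default +50% from day 3) and every interaction in the
    rich medium is a repression (default -50%), in both directions; the
    remaining media carry no planted effects. This is the pattern the
    stress-gradient hypothesis predicts: cooperation under nutrient
    stress, competition under plenty.
    """
    effects = []
    for focal, partner in cross_kingdom_pairs(DEFAULT_ROSTER):
        effects.append(
            EffectSpec(focal, partner, induction_medium, onset_day, induction)
        )
        effects.append(
            EffectSpec(focal, partner, repression_medium, onset_day, repression)
        )
    return GeneratorConfig(noise_cv=noise_cv, effects=tuple(effects), seed=seed)


# -- canonical CSV I/O --------------------------------------------------


def write_area_csv(records: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write the canonical area CSV, recording the seed in a header comment."""
    buf = io.StringIO()
    buf.write(f"# fbinet colony-area table; seed={seed}\n")
    records.to_csv(buf, index=False, columns=AREA_COLUMNS)
    Path(path).write_text(buf.getvalue())


def read_area_csv(path: str | Path) -> pd.DataFrame:
    """Read the canonical area CSV (comment lines ignored)."""
    df = pd.read_csv(path, comment="#", dtype={"focal": str, "partner": str})
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"area CSV missing columns: {missing}")
    df["partner"] = df["partner"].fillna("")
    return df


def validate_area_table(df: pd.DataFrame) -> None:
    """Schema checks with row-level diagnostics."""
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"area table missing columns: {missing}")
    bad = df.index[~(df["area"] > 0)].tolist()
    if bad:
        raise ValueError(f"non-positive areas at rows {bad[:10]}")
    key = ["focal", "partner", "medium", "day", "replicate"]
    dup = df.index[df.duplicated(key)].tolist()
    if dup:
        raise ValueError(f"duplicate (focal, partner, medium, day, replicate) at rows {dup[:10]}")
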