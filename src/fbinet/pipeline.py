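"""End-to-end pipeline: areas -> comparisons -> grades -> networks -> tests.

A single :func:`run_pipeline` call takes either a measured colony-area
CSV or a synthetic generator configuration, runs the full analysis and
writes the report bundle: comparisons CSV, grades CSV, the eight network
files (edge-list CSV + GraphML), the connectivity table, the dominance
table and the per-direction QAP tables, plus a machine-readable manifest
recording every seed and parameter. Identical manifests yield identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .growth_stats import compare_all
from .networks import (
    BipartiteNetwork,
    build_networks,
    connectivity_table,
    export_network,
)
from .permutation import dominance_summary, qap_all_pairs
from .scoring import grade_all
from .strains import DEFAULT_ROSTER, StrainId
from .synthetic import (
    GeneratorConfig,
    generate_dataset,
    read_area_csv,
    validate_area_table,
    write_area_csv,
)


@dataclass
class PipelineConfig:
    """What to analyse and how; exactly one of generator/input_csv."""

    generator: GeneratorConfig | None = None
    input_csv: str | Path | None = None
    roster: Sequence[StrainId] = DEFAULT_ROSTER
    alpha: float = 0.05
    days: Sequence[int] = (3, 5, 7)
    n_perm_location: int = 500
    n_perm_qap: int = 1000
    seed: int | None = None
    location_method: str = "auto"
    out_dir: str | Path | None = None
    overwrite: bool = False

    def validate(self) -> None:
        if (self.generator is None) == (self.input_csv is None):
            raise ValueError("specify exactly one of generator or input_csv")

    def manifest(self) -> dict:
        return {
            "tool": "fbinet",
            "alpha": self.alpha,
            "days": list(self.days),
            "n_perm_location": self.n_perm_location,
            "n_perm_qap": self.n_perm_qap,
            "seed": self.seed,
            "location_method": self.location_method,
            "roster": [{"name": s.name, "kingdom": s.kingdom} for s in self.roster],
            "input_csv": None if self.input_csv is None else str(self.input_csv),
            "generator": None if self.generator is None else self.generator.to_dict(),
        }


@dataclass
class PipelineResult:
    records: pd.DataFrame
    comparisons: pd.DataFrame
    grades: pd.DataFrame
    networks: list[BipartiteNetwork]
    connectivity: pd.DataFrame
    dominance: pd.DataFrame
    qap: dict[str, pd.DataFrame]
    manifest: dict
    out_dir: Path | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config``.

    Incomplete keys (missing controls or missing days) are carried in
    the grade table flagged ``incomplete`` and contribute no network
    link; the pipeline continues on complete keys.
    """
    config.validate()
    if config.generator is not None:
        records = generate_dataset(config.generator)
    else:
        records = read_area_csv(config.input_csv)
    validate_area_table(records)

    comparisons = compare_all(records, alpha=config.alpha)
    grades = grade_all(comparisons, days=config.days)
    media = list(dict.fromkeys(records["medium"]))
    networks = build_networks(grades, roster=config.roster, media=sorted(media))
    conn = connectivity_table(networks)
    dominance = dominance_summary(
        networks,
        alpha=config.alpha,
        n_perm=config.n_perm_location,
        seed=config.seed,
        method=config.location_method,
    )
    directions = sorted({n.direction for n in networks})
    qap = {
        d: qap_all_pairs(networks, d, n_perm=config.n_perm_qap, seed=config.seed)
        for d in directions
    }

    result = PipelineResult(
        records=records,
        comparisons=comparisons,
        grades=grades,
        networks=networks,
        connectivity=conn,
        dominance=dominance,
        qap=qap,
        manifest=config.manifest(),
    )
    if config.out_dir is not None:
        result.out_dir = write_bundle(result, config.out_dir, overwrite=config.overwrite)
    return result


def write_bundle(result: PipelineResult, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write the report bundle under ``out_dir``; refuses to clobber
    an existing bundle unless ``overwrite`` is set."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite/force to replace")
    out.mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)

    seed = result.manifest.get("seed")
    write_area_csv(result.records, out / "areas.csv", seed=seed)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    result.grades.to_csv(out / "grades.csv", index=False)
    for net in result.networks:
        stem = f"{net.medium}_{net.direction}"
        export_network(net, out / "networks" / f"{stem}.csv", format="csv")
        export_network(net, out / "networks" / f"{stem}.graphml", format="graphml")
    result.connectivity.to_csv(out / "connectivity.csv", index=False)
    result.dominance.to_csv(out / "dominance.csv", index=False)
    for direction, table in result.qap.items():
        table.to_csv(out / f"qap_{direction}.csv", index=False)
    manifest_path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    return out


def dominance_report(dominance: pd.DataFrame) -> str:
    """Text rendering of the dominance table: per direction, one line
    per medium with 'median (p)' and a significance star."""
    lines = []
    for direction, grp in dominance.groupby("direction", sort=True):
        lines.append(f"[{direction}]")
        for r in grp.itertuples():
            star = "*" if r.significant else ""
            lines.append(f"  {r.medium}\t{r.median:g} ({r.p_value:.4g}){star}")
    return "\n".join(lines)


def qap_report(qap: pd.DataFrame) -> str:
    """Text rendering of a QAP table: upper-triangular r (p) by media."""
    media = sorted(set(qap["medium_1"]) | set(qap["medium_2"]))
    cell = {
        (r.medium_1, r.medium_2): f"{r.r:.2f} ({r.p_value:.4g})"
        if r.error == ""
        else "undefined"
        for r in qap.itertuples()
    }
    lines = ["\t" + "\t".join(media[1:])]
    for i, m1 in enumerate(media[:-1]):
        row = [m1]
        for m2 in media[1:]:
            row.append(cell.get((m1, m2), ""))
        lines.append("\t".join(row))
    return "\n".join(lines)
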