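"""Per-medium, per-direction bipartite interaction networks.

One directed weighted network per medium per direction: the effects of
fungi on bacteria, and the effects of bacteria on fungi (eight networks
for the default four media). A network is stored as a rectangular
source x target integer matrix of grades; within-kingdom entries are
structurally impossible in the bipartite design, so for the 4-fungus /
5-bacterium roster each direction has exactly 20 possible links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .strains import BACTERIUM, DEFAULT_ROSTER, FUNGUS, StrainId, kingdoms_of

FUNGI_TO_BACTERIA = "fungi_to_bacteria"
BACTERIA_TO_FUNGI = "bacteria_to_fungi"
DIRECTIONS = (FUNGI_TO_BACTERIA, BACTERIA_TO_FUNGI)


@dataclass
class BipartiteNetwork:
    """Directed weighted bipartite network for one medium and direction.

    ``weights[i, j]`` is the graded effect of source strain i on target
    strain j (0 = no link). Sources and targets are fixed in roster
    order so matrix serialization is reproducible.
    """

    medium: str
    direction: str
    sources: tuple[str, ...]
    targets: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=int)
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.weights.shape != (len(self.sources), len(self.targets)):
            raise ValueError("weight matrix shape does not match node lists")
        if np.abs(self.weights).max(initial=0) > 6:
            raise ValueError("grades must lie in [-6, 6]")

    @property
    def n_possible(self) -> int:
        return self.weights.size

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.weights))

    def grades(self) -> np.ndarray:
        """All grades (zeros included), row-major."""
        return self.weights.ravel().copy()


def build_networks(
    grades: pd.DataFrame,
    roster: Sequence[StrainId] = DEFAULT_ROSTER,
    media: Sequence[str] | None = None,
) -> list[BipartiteNetwork]:
    """Assemble one network per medium per direction from a grade table.

    The grade table keys interactions by (focal, partner, medium) where
    ``partner`` is the acting strain and ``focal`` the one whose growth
    responded — so the network entry for source s and target t is the
    grade with partner=s, focal=t. Grades for strains outside the
    roster are rejected; incomplete (ungraded) keys contribute no link.
    """
    kingdoms = kingdoms_of(roster)
    fungi = tuple(s.name for s in roster if s.kingdom == FUNGUS)
    bacteria = tuple(s.name for s in roster if s.kingdom == BACTERIUM)
    unknown = (set(grades["focal"]) | set(grades["partner"])) - set(kingdoms)
    if unknown:
        raise ValueError(f"grades reference strains outside roster: {sorted(unknown)}")
    if media is None:
        media = sorted(grades["medium"].unique())

    graded = grades[grades["grade"].notna()]
    lookup = {
        (r.partner, r.focal, r.medium): int(r.grade) for r in graded.itertuples()
    }

    nets = []
    for medium in media:
        for direction, sources, targets in (
            (FUNGI_TO_BACTERIA, fungi, bacteria),
            (BACTERIA_TO_FUNGI, bacteria, fungi),
        ):
            w = np.zeros((len(sources), len(targets)), dtype=int)
            for i, s in enumerate(sources):
                for j, t in enumerate(targets):
                    w[i, j] = lookup.get((s, t, medium), 0)
            nets.append(BipartiteNetwork(medium, direction, sources, targets, w))
    return nets


def connectivity(net: BipartiteNetwork) -> float:
    """Percentage of possible links that are present (nonzero grade)."""
    if net.n_possible == 0:
        return 0.0
    return 100.0 * net.n_links / net.n_possible


def connectivity_table(networks: Iterable[BipartiteNetwork]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "medium": n.medium,
                "direction": n.direction,
                "n_links": n.n_links,
                "n_possible": n.n_possible,
                "connectivity_pct": connectivity(n),
            }
            for n in networks
        ]
    )


# -- serialization ------------------------------------------------------

EDGE_COLUMNS = ["source", "target", "medium", "direction", "grade", "sign"]


def _sign_label(grade: int) -> str:
    return "induction" if grade > 0 else "repression"


def to_edgelist(net: BipartiteNetwork) -> pd.DataFrame:
    """Edge-list frame of the nonzero links (signed grade + sign label)."""
    rows = [
        {
            "source": net.sources[i],
            "target": net.targets[j],
            "medium": net.medium,
            "direction": net.direction,
            "grade": int(net.weights[i, j]),
            "sign": _sign_label(net.weights[i, j]),
        }
        for i, j in zip(*np.nonzero(net.weights))
    ]
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def from_edgelist(
    edges: pd.DataFrame,
    sources: Sequence[str],
    targets: Sequence[str],
    medium: str,
    direction: str,
) -> BipartiteNetwork:
    """Rebuild a network from its edge list plus the node rosters
    (absent edges are zero-weight, so isolated nodes need the roster)."""
    w = np.zeros((len(sources), len(targets)), dtype=int)
    si = {s: i for i, s in enumerate(sources)}
    ti = {t: j for j, t in enumerate(targets)}
    for r in edges.itertuples():
        w[si[r.source], ti[r.target]] = int(r.grade)
    return BipartiteNetwork(medium, direction, tuple(sources), tuple(targets), w)


def to_graph(net: BipartiteNetwork) -> nx.DiGraph:
    """networkx view with weight and sign attributes on edges."""
    g = nx.DiGraph(
        medium=net.medium,
        direction=net.direction,
        sources=",".join(net.sources),
        targets=",".join(net.targets),
    )
    for s in net.sources:
        g.add_node(s, role="source")
    for t in net.targets:
        g.add_node(t, role="target")
    for i, j in zip(*np.nonzero(net.weights)):
        grade = int(net.weights[i, j])
        g.add_edge(
            net.sources[i], net.targets[j], weight=grade, sign=_sign_label(grade)
        )
    return g


def from_graph(g: nx.DiGraph) -> BipartiteNetwork:
    sources = tuple(g.graph["sources"].split(","))
    targets = tuple(g.graph["targets"].split(","))
    w = np.zeros((len(sources), len(targets)), dtype=int)
    si = {s: i for i, s in enumerate(sources)}
    ti = {t: j for j, t in enumerate(targets)}
    for u, v, data in g.edges(data=True):
        w[si[u], ti[v]] = int(data["weight"])
    return BipartiteNetwork(g.graph["medium"], g.graph["direction"], sources, targets, w)


def export_network(net: BipartiteNetwork, path: str | Path, format: str = "csv") -> None:
    """Write a network as an edge-list CSV or GraphML file.

    Export followed by :func:`import_network` reproduces the weight
    matrix exactly.
    """
    path = Path(path)
    if format == "csv":
        to_edgelist(net).to_csv(path, index=False)
    elif format == "graphml":
        nx.write_graphml(to_graph(net), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def import_network(
    path: str | Path,
    format: str = "csv",
    sources: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
    medium: str | None = None,
    direction: str | None = None,
) -> BipartiteNetwork:
    """Read a network written by :func:`export_network`.

    The CSV edge list stores only present links, so the node rosters
    (and medium/direction, if the file has no edges) must be supplied;
    GraphML is self-describing.
    """
    path = Path(path)
    if format == "csv":
        edges = pd.read_csv(path)
        if sources is None or targets is None:
            raise ValueError("CSV import needs explicit sources/targets rosters")
        if len(edges):
            medium = edges["medium"].iloc[0]
            direction = edges["direction"].iloc[0]
        if medium is None or direction is None:
            raise ValueError("empty edge list: medium and direction must be supplied")
        return from_edgelist(edges, sources, targets, medium, direction)
    if format == "graphml":
        return from_graph(nx.read_graphml(path))
    raise ValueError(f"unknown network format {format!r}")
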