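"""Assemble the eight bipartite interaction networks (4 media x 2
directions) for the stress-gradient dataset and compute connectivity.

Writes edge-list CSV and GraphML files under results/networks_stress/
plus results/connectivity_stress.csv.
"""

from pathlib import Path

import pandas as pd

import fbinet as fb
from fbinet.networks import connectivity_table, export_network

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    grades = pd.read_csv(OUT / "grades_stress.csv")
    nets = fb.build_networks(grades)
    netdir = OUT / "networks_stress"
    netdir.mkdir(exist_ok=True)
    for net in nets:
        stem = f"{net.medium}_{net.direction}"
        export_network(net, netdir / f"{stem}.csv", format="csv")
        export_network(net, netdir / f"{stem}.graphml", format="graphml")
    conn = connectivity_table(nets)
    conn.to_csv(OUT / "connectivity_stress.csv", index=False)
    print(conn.to_string(index=False))


if __name__ == "__main__":
    main()
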