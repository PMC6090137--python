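"""Permutation inference on the stress-gradient networks.

Per network: the sign-flip location test of the grades against median 0
(dominance of inductions vs repressions). Per direction: QAP
correlations between every pair of media. Writes
results/dominance_stress.csv and results/qap_{direction}_stress.csv.
"""

from pathlib import Path

import pandas as pd

import fbinet as fb
from fbinet.pipeline import dominance_report, qap_report

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    grades = pd.read_csv(OUT / "grades_stress.csv")
    nets = fb.build_networks(grades)

    dominance = fb.dominance_summary(nets, alpha=0.05, seed=SEED)
    dominance.to_csv(OUT / "dominance_stress.csv", index=False)
    print("Dominance of inductions vs repressions (median grade, p):")
    print(dominance_report(dominance))

    for direction in ("fungi_to_bacteria", "bacteria_to_fungi"):
        table = fb.qap_all_pairs(nets, direction, n_perm=1000, seed=SEED)
        table.to_csv(OUT / f"qap_{direction}_stress.csv", index=False)
        print(f"\nQAP correlations between media [{direction}]: r (p)")
        print(qap_report(table))


if __name__ == "__main__":
    main()
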