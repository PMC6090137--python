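"""Grade every (focal, partner, medium) day-3/5/7 significance pattern
to a signed interaction strength in [-6, +6].

Reads the comparisons from 02, writes results/grades_{null,stress}.csv
and summarizes the grade distribution per medium.
"""

from pathlib import Path

import pandas as pd

import fbinet as fb
from fbinet.scoring import grade_all

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("null", "stress"):
        comparisons = pd.read_csv(OUT / f"comparisons_{name}.csv")
        grades = grade_all(comparisons)
        grades.to_csv(OUT / f"grades_{name}.csv", index=False)
        nonzero = grades[grades["grade"] != 0]
        print(f"{name}: {len(grades)} keys, {len(nonzero)} nonzero grades")
        if len(nonzero):
            by_medium = nonzero.groupby("medium")["grade"].agg(["count", "median"])
            print(by_medium.to_string())


if __name__ == "__main__":
    main()
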