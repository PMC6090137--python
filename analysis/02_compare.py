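"""Welch comparisons of every co-culture cell against its monoculture
control, per organism, partner, medium and day.

Reads the area tables from 01, writes results/comparisons_{null,stress}.csv
and reports how many of the 480 comparisons are significant at 0.05.
"""

from pathlib import Path

import fbinet as fb

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("null", "stress"):
        records = fb.read_area_csv(OUT / f"areas_{name}.csv")
        comparisons = fb.compare_all(records, alpha=0.05)
        comparisons.to_csv(OUT / f"comparisons_{name}.csv", index=False)
        n_sig = (comparisons["sign_call"] != 0).sum()
        n_pos = (comparisons["sign_call"] == 1).sum()
        print(
            f"{name}: {len(comparisons)} comparisons, {n_sig} significant "
            f"({n_pos} inductions, {n_sig - n_pos} repressions)"
        )


if __name__ == "__main__":
    main()
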