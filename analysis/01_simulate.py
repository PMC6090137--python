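"""Simulate the two study designs used throughout the analysis.

Writes results/areas_null.csv (no planted effects: pure replicate noise
around the monoculture baselines) and results/areas_stress.csv (the
stress-gradient scenario: every cross-kingdom interaction on the
low-nutrient MM medium is a +50% induction and every interaction on
rich PDA a -50% repression, both directions, CV 10%, triplicates).
"""

from pathlib import Path

import fbinet as fb

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for name, cfg in [
        ("null", fb.null_config(seed=SEED)),
        ("stress", fb.stress_gradient_config(seed=SEED)),
    ]:
        records = fb.generate_dataset(cfg)
        path = OUT / f"areas_{name}.csv"
        fb.write_area_csv(records, path, seed=SEED)
        cfg.to_file(OUT / f"config_{name}.yaml")
        n_mono = (records["partner"] == "").sum()
        print(
            f"{name}: {len(records)} records ({n_mono} monoculture, "
            f"{len(records) - n_mono} co-culture) -> {path.name}"
        )


if __name__ == "__main__":
    main()
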