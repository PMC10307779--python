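#!/usr/bin/env python
"""Derive the 14 behavioral outcome measures (8 pre-surgery, 6 post-surgery)
for every animal and write the wide measures table.

Reads results/cohort/, writes results/measures.csv (+ transform-flag
sidecar) and prints group means +/- SEM per measure.
"""

from pathlib import Path

import numpy as np

from ethopharm import io
from ethopharm.measures import build_measure_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    dataset = io.read_dataset(ROOT / "cohort")
    table = build_measure_table(dataset)
    path = io.write_measures(table, ROOT / "measures.csv")
    print(f"measures for {len(table.data)} animals -> {path}")
    flag = table.transform_flags["Rate of loco habituation"]
    print(f"square-root transform applied to habituation slopes: {flag}")
    print(f"{'measure':42s} {'mean':>10s} {'SEM':>8s}")
    for measure in table.data.columns:
        vals = table.data[measure].dropna()
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        print(f"{measure:42s} {vals.mean():10.1f} {sem:8.1f}")


if __name__ == "__main__":
    main()
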