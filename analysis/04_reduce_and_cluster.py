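#!/usr/bin/env python
"""Data-reduction analysis: Pearson correlation matrix (AOE-ordered),
1-|r| distance, 2-D classical MDS, and k-means with an index vote on k.

Runs the pre-surgery panel (k searched over 2-6) and the combined
pre+post-surgery panel (k over 2-4); writes all artifacts under results/.
"""

from pathlib import Path

from ethopharm import io
from ethopharm.cli import _write_panel
from ethopharm.cluster import run_clustering
from ethopharm.measures import ALL_MEASURES, PRE_MEASURES

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    table = io.read_measures(ROOT / "measures.csv")
    for name, columns, (k_min, k_max) in [
        ("pre_surgery", list(PRE_MEASURES), (2, 6)),
        ("combined", list(ALL_MEASURES), (2, 4)),
    ]:
        report, mds, corr = run_clustering(table, columns, k_min=k_min,
                                           k_max=k_max, seed=SEED)
        _write_panel(ROOT / name, report, mds, corr)
        print(f"[{name}] k search {k_min}-{k_max}: chose k = {report.k} "
              f"(votes {report.votes})")
        print(f"  AOE display order: {', '.join(corr.order)}")
        clusters: dict[int, list[str]] = {}
        for measure, lab in report.labels.items():
            clusters.setdefault(lab, []).append(measure)
        for lab, members in sorted(clusters.items()):
            print(f"  cluster {lab}: {', '.join(members)}")
        print(f"  MDS reconstruction error (1-|r| is non-Euclidean): "
              f"{mds.recon_error:.3f}\n")


if __name__ == "__main__":
    main()
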