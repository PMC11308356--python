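#!/usr/bin/env python
"""ROH islands and cross-breed overlap.

Computes per-SNP ROH incidence on each breed's shared marker set, calls
islands as maximal stretches shared by more than 70% of the breed's
animals, exports them as TSV and BED, and intersects the two breeds'
island sets to find candidate regions under selection in both.
"""

import argparse
from pathlib import Path

import pandas as pd

from equidiv import (
    QCConfig,
    apply_qc,
    call_islands,
    export_bed,
    intersect_markers,
    island_incidence,
    islands_to_frame,
    overlap_islands,
    read_plink,
)
from equidiv.roh_stats import islands_to_intervals

SIM = Path("results/sim")
OUT = Path("results/analysis")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--threshold", type=float, default=0.70)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    ga, _ = apply_qc(read_plink(SIM / "breed_a"), QCConfig.profile("roh"))
    gb, _ = apply_qc(read_plink(SIM / "breed_b"), QCConfig.profile("roh"))
    ga, gb = intersect_markers(ga, gb, key="position")

    sets = {}
    for name, g in (("breed_a", ga), ("breed_b", gb)):
        runs = pd.read_csv(OUT / f"{name}.roh.tsv", sep="\t",
                           dtype={"chrom": str})
        inc = island_incidence(runs, g)
        inc.to_csv(OUT / f"{name}.incidence.tsv", sep="\t", index=False)
        islands = call_islands(inc, args.threshold)
        sets[name] = islands
        islands_to_frame(islands).to_csv(
            OUT / f"{name}.islands.tsv", sep="\t", index=False
        )
        export_bed(islands_to_intervals(islands), OUT / f"{name}.islands.bed")
        chroms = sorted({i.chrom for i in islands}, key=int)
        peak = max((i.peak_incidence for i in islands), default=float("nan"))
        print(
            f"{name}: {len(islands)} islands above "
            f"{100 * args.threshold:.0f}% incidence on chromosomes "
            f"{','.join(chroms) or '-'} (peak incidence {peak:.2f})"
        )

    shared = overlap_islands(sets["breed_a"], sets["breed_b"])
    shared.to_csv(OUT / "islands_shared.tsv", sep="\t", index=False)
    if len(shared):
        print(
            f"shared islands: {len(shared)} overlapping pairs on chromosomes "
            f"{','.join(sorted(shared['chrom'].unique(), key=int))}; "
            f"largest overlap {shared['overlap_bp'].max():,} bp"
        )
    else:
        print("shared islands: none")


if __name__ == "__main__":
    main()
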