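#!/usr/bin/env python
"""Pedigree completeness, inbreeding and coancestry-rate Ne.

Analyses breed_a's recorded pedigree: discrete generation equivalents as a
completeness measure, Wright's inbreeding coefficient F_PED, the effective
population size from the mean rate of increase in coancestry over the
sampled cohort, and the correlation between genomic (F_ROH) and pedigree
(F_PED) inbreeding.
"""

import argparse
from pathlib import Path

import pandas as pd

from equidiv import Pedigree, froh_fped_correlation, ne_coancestry, pedigree_summary

SIM = Path("results/sim")
OUT = Path("results/analysis")


def main():
    argparse.ArgumentParser(description=__doc__).parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    ped = Pedigree.read(SIM / "breed_a.pedigree.tsv")
    froh_table = pd.read_csv(OUT / "breed_a.froh_100kb.tsv", sep="\t")
    cohort = [s for s in froh_table["sample_id"] if s in ped.records]

    summary = pedigree_summary(ped, cohort)
    summary.to_csv(OUT / "breed_a.pedigree.tsv", sep="\t", index=False)
    print(
        f"cohort of {len(cohort)}: mean generation equivalents "
        f"{summary['ge'].mean():.2f} (range {summary['ge'].min():.2f}-"
        f"{summary['ge'].max():.2f}); mean F_PED = {summary['f_ped'].mean():.3f}"
    )

    ne, rate = ne_coancestry(ped, cohort)
    Path(OUT / "breed_a.pedigree_ne.txt").write_text(
        f"ne_coancestry\t{ne:.2f}\nmean_delta_c\t{rate:.6f}\n"
    )
    print(f"coancestry-rate Ne = {ne:.1f} (mean delta_c = {rate:.5f})")

    r, p = froh_fped_correlation(froh_table, summary)
    Path(OUT / "breed_a.froh_fped.txt").write_text(f"r\t{r:.4f}\np\t{p:.3e}\n")
    print(f"F_ROH ~ F_PED: r = {r:.2f} (p = {p:.2e})")


if __name__ == "__main__":
    main()
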