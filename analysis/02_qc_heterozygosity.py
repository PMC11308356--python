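#!/usr/bin/env python
"""Quality control, marker intersection, PCA and heterozygosity.

Loads the two simulated breeds, applies both QC profiles (ROH profile
without MAF pruning; diversity profile with MAF >= 0.05), intersects the
breeds' marker maps for the joint analyses, runs the PCA outlier check on
the combined data, and reports observed and expected heterozygosity per
breed.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from equidiv import (
    GenotypeMatrix,
    QCConfig,
    apply_qc,
    expected_het,
    intersect_markers,
    observed_het,
    pca,
    read_plink,
)

SIM = Path("results/sim")
OUT = Path("results/analysis")


def main():
    argparse.ArgumentParser(description=__doc__).parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    breeds = {}
    for name in ("breed_a", "breed_b"):
        g = read_plink(SIM / name, metadata=SIM / f"{name}.meta.tsv")
        for profile in ("roh", "diversity"):
            gq, report = apply_qc(g, QCConfig.profile(profile))
            report.to_frame().to_csv(
                OUT / f"{name}.qc_{profile}.tsv", sep="\t", index=False
            )
            breeds[(name, profile)] = gq
        print(
            f"{name}: {g.n_markers} SNPs -> ROH profile "
            f"{breeds[(name, 'roh')].n_markers}, diversity profile "
            f"{breeds[(name, 'diversity')].n_markers}"
        )

    # joint marker set across breeds (ROH profile), as used for islands
    a, b = intersect_markers(
        breeds[("breed_a", "roh")], breeds[("breed_b", "roh")], key="position"
    )
    print(f"shared SNPs for the combined analyses: {a.n_markers}")
    a.markers[["chrom", "snp_id", "pos_bp"]].to_csv(
        OUT / "shared_markers.tsv", sep="\t", index=False
    )

    # PCA on the combined diversity-profile data (outlier / mix-up check)
    ad, bd = intersect_markers(
        breeds[("breed_a", "diversity")], breeds[("breed_b", "diversity")],
        key="position",
    )
    combined = GenotypeMatrix(
        pd.concat([ad.samples, bd.samples], ignore_index=True),
        ad.markers,
        np.vstack([ad.calls, bd.calls]),
        ad.autosomes,
    )
    coords = pca(combined, k=2)
    coords["population"] = combined.samples["population"].to_numpy()
    coords.to_csv(OUT / "pca.tsv", sep="\t", index=False)
    by_pop = coords.groupby("population")["PC1"]
    gap = by_pop.min().max() - by_pop.max().min()
    print(f"PCA: breeds separate on PC1 (gap between clusters: {gap:.1f})")

    rows = []
    for name in ("breed_a", "breed_b"):
        gq = breeds[(name, "diversity")]
        het = observed_het(gq)
        het.to_csv(OUT / f"{name}.het.tsv", sep="\t", index=False)
        cohort = expected_het(gq)
        rows.append(
            {
                "population": name,
                "mean_h_obs": round(cohort.mean_h_obs, 4),
                "mean_h_exp": round(cohort.mean_h_exp, 4),
                "h_obs_min": round(het["h_obs"].min(), 4),
                "h_obs_max": round(het["h_obs"].max(), 4),
                "n_samples": cohort.n_samples,
                "n_snps": cohort.n_snps,
            }
        )
        print(
            f"{name}: H_O = {cohort.mean_h_obs:.3f} "
            f"(range {het['h_obs'].min():.3f}-{het['h_obs'].max():.3f}), "
            f"H_E = {cohort.mean_h_exp:.3f}"
        )
    pd.DataFrame(rows).to_csv(OUT / "heterozygosity.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
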