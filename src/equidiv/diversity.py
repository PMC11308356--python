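"""Observed and expected heterozygosity.

Per sample: H_O = n_het / n_nonmissing, plus the method-of-moments
inbreeding estimate F_hat = (O_hom - E_hom) / (n - E_hom) familiar from
PLINK's ``--het`` (expected homozygosity under Hardy-Weinberg from sample
allele frequencies, with the small-sample 2n/(2n-1) correction).

Per cohort: H_E is the mean over markers of the per-marker expected
heterozygosity 2p(1-p), optionally small-sample corrected.  Monomorphic
markers contribute 0 and stay in the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_plink import MISSING, GenotypeMatrix


@dataclass
class CohortHet:
    mean_h_obs: float
    mean_h_exp: float
    n_samples: int
    n_snps: int


def observed_het(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample observed heterozygosity.

    Returns a frame with columns ``sample_id, n_nonmissing, n_het, h_obs,
    f_hat``.  Samples with zero non-missing calls get ``h_obs = NaN`` and
    are to be excluded from cohort means.
    """
    obs = g.calls != MISSING
    het = g.calls == 1
    n_obs = obs.sum(axis=1)
    n_het = het.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_obs = np.where(n_obs > 0, n_het / np.maximum(n_obs, 1), np.nan)

    # expected homozygous count per sample under HWE, over its observed markers
    p = g.allele_freq()
    n_alleles = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(n_alleles > 1, n_alleles / (n_alleles - 1.0), 0.0)
    e_het_marker = 2.0 * p * (1.0 - p) * corr
    e_hom = (obs * (1.0 - e_het_marker)).sum(axis=1)
    o_hom = n_obs - n_het
    denom = n_obs - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f_hat = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)

    return pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "n_nonmissing": n_obs,
            "n_het": n_het,
            "h_obs": h_obs,
            "f_hat": f_hat,
        }
    )


def expected_het(g: GenotypeMatrix, correction: str = "small_sample") -> CohortHet:
    """Cohort heterozygosity summary.

    ``correction`` is "small_sample" (multiply each marker's 2p(1-p) by
    2n/(2n-1), n = non-missing allele count) or "none".
    """
    if correction not in ("none", "small_sample"):
        raise ValueError(f"unknown correction {correction!r}")
    p = g.allele_freq()
    e_het = 2.0 * p * (1.0 - p)
    if correction == "small_sample":
        n_alleles = 2.0 * (g.calls != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(n_alleles > 1, n_alleles / (n_alleles - 1.0), 0.0)
        e_het = e_het * corr
    ho = observed_het(g)["h_obs"]
    return CohortHet(
        mean_h_obs=float(np.nanmean(ho)) if len(ho) else float("nan"),
        mean_h_exp=float(np.mean(e_het)) if len(e_het) else float("nan"),
        n_samples=g.n_samples,
        n_snps=g.n_markers,
    )
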