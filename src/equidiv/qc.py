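"""Quality control of array genotypes and PCA outlier screening.

Two QC profiles are used downstream, mirroring common practice for SNP-array
diversity studies:

* ``roh`` profile — call-rate filters only.  No minor-allele-frequency (MAF),
  Hardy-Weinberg or LD pruning, so that runs of homozygosity are not biased
  by the removal of low-MAF markers.
* ``diversity`` profile — call-rate filters plus MAF >= 0.05, for
  heterozygosity and LD-based effective-population-size work.

Filters are applied in a declared order (autosome restriction happens at
load; then SNP call-rate, sample call-rate, optional MAF), sweeping to a
fixed point so the surviving matrix satisfies all thresholds at once, and
every stage's removal count is recorded in the :class:`QCReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_plink import MISSING, GenotypeMatrix


@dataclass
class QCConfig:
    """Thresholds for genotype quality control.

    ``max_snp_missing_rate`` / ``max_sample_missing_rate`` follow the usual
    "> threshold is removed" convention; ``min_maf`` of ``None`` disables
    MAF pruning (the ROH profile).
    """

    max_snp_missing_rate: float = 0.10
    max_sample_missing_rate: float = 0.10
    min_maf: float | None = None

    def __post_init__(self) -> None:
        for r in (self.max_snp_missing_rate, self.max_sample_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("missing-rate thresholds must be in [0, 1]")
        if self.min_maf is not None and not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")

    @classmethod
    def profile(cls, name: str) -> "QCConfig":
        """The two named profiles: "roh" (no MAF) and "diversity" (MAF 0.05)."""
        if name == "roh":
            return cls(min_maf=None)
        if name == "diversity":
            return cls(min_maf=0.05)
        raise ValueError(f"unknown QC profile {name!r}")


@dataclass
class QCReport:
    """Per-stage removal counts; ``in - removed == out`` on both axes."""

    n_snps_in: int
    n_samples_in: int
    n_snps_out: int = 0
    n_samples_out: int = 0
    removed_by_stage: dict[str, int] = field(default_factory=dict)
    removed_sample_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snps_in", self.n_snps_in), ("samples_in", self.n_samples_in)]
        rows += list(self.removed_by_stage.items())
        rows += [("snps_out", self.n_snps_out), ("samples_out", self.n_samples_out)]
        return pd.DataFrame(rows, columns=["stage", "count"])


def apply_qc(g: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers and samples per ``cfg``; returns the surviving matrix
    and a report of what each stage removed.

    Order within each sweep: SNP call-rate, then sample call-rate, then MAF
    (recomputed on the current matrix).  Raises if nothing survives.
    """
    report = QCReport(n_snps_in=g.n_markers, n_samples_in=g.n_samples)
    report.removed_by_stage = {"snp_call_rate": 0, "sample_call_rate": 0, "maf": 0}

    # sweep snp -> sample -> maf until a fixed point: each removal can shift
    # the other axis's rates, and the contract is that the returned matrix
    # satisfies every threshold simultaneously (which also makes apply_qc
    # idempotent).  Two sweeps suffice in practice.
    changed = True
    while changed:
        changed = False
        miss = g.calls == MISSING

        snp_rate = miss.mean(axis=0) if g.n_samples else np.zeros(g.n_markers)
        keep_snp = snp_rate <= cfg.max_snp_missing_rate
        if not keep_snp.all():
            report.removed_by_stage["snp_call_rate"] += int((~keep_snp).sum())
            g = g.take_markers(np.flatnonzero(keep_snp))
            miss = miss[:, keep_snp]
            changed = True

        sample_rate = miss.mean(axis=1) if g.n_markers else np.zeros(g.n_samples)
        keep_s = sample_rate <= cfg.max_sample_missing_rate
        if not keep_s.all():
            report.removed_by_stage["sample_call_rate"] += int((~keep_s).sum())
            report.removed_sample_ids += [
                sid for sid, k in zip(g.sample_ids, keep_s) if not k
            ]
            g = g.take_samples(np.flatnonzero(keep_s))
            changed = True

        if cfg.min_maf is not None:
            p = g.allele_freq()
            maf = np.minimum(p, 1.0 - p)
            keep_maf = maf >= cfg.min_maf
            if not keep_maf.all():
                report.removed_by_stage["maf"] += int((~keep_maf).sum())
                g = g.take_markers(np.flatnonzero(keep_maf))
                changed = True

        if g.n_markers == 0 or g.n_samples == 0:
            raise ValueError("QC removed all markers or all samples")
    report.n_snps_out = g.n_markers
    report.n_samples_out = g.n_samples
    return g, report


def pca(g: GenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """Principal components of standardized genotypes, for outlier checks.

    Missing calls are mean-imputed per marker, then each marker is scaled as
    (x - 2p) / sqrt(2p(1-p)); monomorphic markers are excluded (their scale
    is zero).  Returns a frame with ``sample_id`` and columns PC1..PCk.
    Coordinates are deterministic up to sign.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = g.calls.astype(np.float64)
    obs = g.calls != MISSING
    p = g.allele_freq()
    x[~obs] = (2.0 * p)[np.newaxis, :].repeat(g.n_samples, axis=0)[~obs]
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = scale > 0
    z = (x[:, poly] - 2.0 * p[poly]) / scale[poly]
    z -= z.mean(axis=0)
    # SVD of the centered matrix; projections of samples on the top axes
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k_eff = min(k, s.size)
    coords = u[:, :k_eff] * s[:k_eff]
    # sign convention: largest-|loading| coordinate positive
    for j in range(k_eff):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    out = pd.DataFrame(coords, columns=[f"PC{j + 1}" for j in range(k_eff)])
    out.insert(0, "sample_id", g.sample_ids)
    return out
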