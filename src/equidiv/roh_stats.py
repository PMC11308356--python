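"""Statistics over detected runs of homozygosity.

Covers the genomic inbreeding coefficient F_ROH (genome, per chromosome and
per length class), the descriptive per-class ROH table, per-SNP ROH
incidence and island calling at an incidence threshold, cross-population
island overlap, the genotype-free coverage validation of the detection
settings, and the F_ROH ~ F_PED correlation.

F_ROH for a sample is the summed length of its runs divided by the
autosomal genome length L_auto.  L_auto defaults to the SNP-covered span of
the marker map (sum over autosomes of last - first SNP position) and can be
pinned to a constant (e.g. 2281 Mb for the 670K equine array) to replicate
published analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_plink import GenotypeMatrix, IntervalRecord
from .roh import LENGTH_CLASS_LABELS, ROHParams, classify_length


@dataclass
class GenomeLengths:
    """Per-autosome SNP-covered lengths and their total L_auto (bp)."""

    per_chrom: dict[str, int]
    l_auto: int

    @classmethod
    def from_marker_map(
        cls, markers: pd.DataFrame, l_auto_override_bp: int | None = None
    ) -> "GenomeLengths":
        per = {
            str(c): int(grp["pos_bp"].max() - grp["pos_bp"].min())
            for c, grp in markers.groupby("chrom", sort=False)
        }
        total = l_auto_override_bp if l_auto_override_bp else sum(per.values())
        if total <= 0:
            raise ValueError("L_auto must be positive")
        return cls(per_chrom=per, l_auto=int(total))


def froh(
    runs: pd.DataFrame,
    sample_ids: list[str],
    lengths: GenomeLengths,
) -> pd.DataFrame:
    """Per-sample F_ROH: total, per length class, per chromosome.

    Every sample in ``sample_ids`` appears (zero runs -> F_ROH 0).  Columns:
    ``sample_id, froh_total, froh_<class>..., froh_chr_<c>...``.  Per-class
    values sum exactly to the total; per-chromosome values are relative to
    that chromosome's covered length.
    """
    unknown = set(runs["chrom"]) - set(lengths.per_chrom) if len(runs) else set()
    if unknown:
        raise ValueError(f"runs on chromosomes absent from lengths: {sorted(unknown)}")
    out = pd.DataFrame({"sample_id": sample_ids})
    if len(runs):
        runs = runs.copy()
        if "length_class" not in runs:
            runs["length_class"] = classify_length(runs["length_bp"].to_numpy())
        by_total = runs.groupby("sample_id")["length_bp"].sum() / lengths.l_auto
        out["froh_total"] = out["sample_id"].map(by_total).fillna(0.0)
        for cls_label in LENGTH_CLASS_LABELS:
            sub = runs[runs["length_class"] == cls_label]
            s = sub.groupby("sample_id")["length_bp"].sum() / lengths.l_auto
            out[f"froh_{cls_label}"] = out["sample_id"].map(s).fillna(0.0)
        for chrom, clen in lengths.per_chrom.items():
            sub = runs[runs["chrom"] == chrom]
            s = sub.groupby("sample_id")["length_bp"].sum() / max(clen, 1)
            out[f"froh_chr_{chrom}"] = out["sample_id"].map(s).fillna(0.0)
    else:
        out["froh_total"] = 0.0
        for cls_label in LENGTH_CLASS_LABELS:
            out[f"froh_{cls_label}"] = 0.0
        for chrom in lengths.per_chrom:
            out[f"froh_chr_{chrom}"] = 0.0
    return out


def froh_summary(froh_table: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean/min/max/sd of F_ROH, total and per length class."""
    rows = []
    for col in ["froh_total"] + [f"froh_{c}" for c in LENGTH_CLASS_LABELS]:
        v = froh_table[col].to_numpy()
        rows.append(
            {
                "quantity": col,
                "mean": float(np.mean(v)),
                "min": float(np.min(v)),
                "max": float(np.max(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def descriptive_table(runs: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Per-length-class descriptive ROH table.

    Columns: ``length_class, n_ind`` (animals with >= 1 run in the class),
    ``n_roh`` (total runs), ``roh_pct`` (share of all runs, %), ``s_roh``
    (mean runs per animal carrying them), ``l_roh_mb`` (mean run length, Mb).
    """
    total = len(runs)
    rows = []
    for cls_label in LENGTH_CLASS_LABELS:
        sub = runs[runs["length_class"] == cls_label] if total else runs
        n_roh = len(sub)
        n_ind = sub["sample_id"].nunique() if n_roh else 0
        rows.append(
            {
                "length_class": cls_label,
                "n_ind": n_ind,
                "n_roh": n_roh,
                "roh_pct": 100.0 * n_roh / total if total else 0.0,
                "s_roh": n_roh / n_ind if n_ind else 0.0,
                "l_roh_mb": sub["length_bp"].mean() / 1e6 if n_roh else 0.0,
            }
        )
    return pd.DataFrame(rows)


def island_incidence(runs: pd.DataFrame, g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP fraction of samples whose ROH covers the SNP.

    The denominator is every sample in the registry, not only carriers.
    Returns the marker map plus an ``incidence`` column.
    """
    inc = np.zeros(g.n_markers)
    pos_all = g.markers["pos_bp"].to_numpy()
    for chrom in g.autosomes:
        idx = g.chrom_indices(chrom)
        if idx.size == 0:
            continue
        pos = pos_all[idx]
        diff = np.zeros(idx.size + 1, dtype=np.int64)
        sub = runs[runs["chrom"] == chrom] if len(runs) else runs
        for row in sub.itertuples(index=False):
            a = np.searchsorted(pos, row.start_bp, side="left")
            b = np.searchsorted(pos, row.end_bp, side="right")
            # runs of one sample are disjoint, so +-1 never double-counts
            diff[a] += 1
            diff[b] -= 1
        inc[idx] = np.cumsum(diff[:-1]) / max(g.n_samples, 1)
    out = g.markers[["chrom", "snp_id", "pos_bp"]].copy()
    out["incidence"] = inc
    return out


@dataclass
class RohIsland:
    chrom: str
    start_bp: int
    end_bp: int
    length_kb: float
    n_snp: int
    peak_incidence: float
    threshold: float


def call_islands(
    incidence: pd.DataFrame, threshold: float = 0.70
) -> list[RohIsland]:
    """Maximal stretches of SNPs with incidence strictly above ``threshold``.

    Island coordinates are the first and last SNP of the stretch.
    """
    islands: list[RohIsland] = []
    for chrom, grp in incidence.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        inc = grp["incidence"].to_numpy()
        above = inc > threshold
        if not above.any():
            continue
        starts = np.flatnonzero(above & np.concatenate(([True], ~above[:-1])))
        ends = np.flatnonzero(above & np.concatenate((~above[1:], [True])))
        for i, j in zip(starts, ends):
            islands.append(
                RohIsland(
                    chrom=str(chrom),
                    start_bp=int(pos[i]),
                    end_bp=int(pos[j]),
                    length_kb=float(pos[j] - pos[i]) / 1e3,
                    n_snp=int(j - i + 1),
                    peak_incidence=float(inc[i : j + 1].max()),
                    threshold=threshold,
                )
            )
    return islands


def islands_to_frame(islands: list[RohIsland]) -> pd.DataFrame:
    cols = ["chrom", "start_bp", "end_bp", "length_kb", "n_snp",
            "peak_incidence", "threshold"]
    return pd.DataFrame([vars(i) for i in islands], columns=cols)


def islands_to_intervals(islands: list[RohIsland]) -> list[IntervalRecord]:
    return [
        IntervalRecord(
            i.chrom, i.start_bp, i.end_bp,
            name=f"island_{i.chrom}_{i.start_bp}", score=i.peak_incidence,
        )
        for i in islands
    ]


def overlap_islands(
    a: list[RohIsland], b: list[RohIsland]
) -> pd.DataFrame:
    """All same-chromosome island pairs with positive bp overlap.

    Columns: chrom, a_start/end, b_start/end, shared_start/end, overlap_bp.
    """
    rows = []
    for ia in a:
        for ib in b:
            if ia.chrom != ib.chrom:
                continue
            s = max(ia.start_bp, ib.start_bp)
            e = min(ia.end_bp, ib.end_bp)
            if s < e:
                rows.append(
                    {
                        "chrom": ia.chrom,
                        "a_start_bp": ia.start_bp, "a_end_bp": ia.end_bp,
                        "b_start_bp": ib.start_bp, "b_end_bp": ib.end_bp,
                        "shared_start_bp": s, "shared_end_bp": e,
                        "overlap_bp": e - s,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "a_start_bp", "a_end_bp", "b_start_bp", "b_end_bp",
                 "shared_start_bp", "shared_end_bp", "overlap_bp"],
    )


def coverage_validation(
    markers: pd.DataFrame, params: ROHParams, lengths: GenomeLengths | None = None
) -> float:
    """Fraction of L_auto on which the detection settings could call a run.

    Genotype-free scan: marker stretches are split at gaps above
    ``max_gap_bp``; each stretch meeting the min-SNP, min-length and density
    constraints contributes its span.  A value near 1 validates the settings
    for the map at hand.
    """
    if lengths is None:
        lengths = GenomeLengths.from_marker_map(markers)
    covered = 0
    for _, grp in markers.groupby("chrom", sort=False):
        pos = np.sort(grp["pos_bp"].to_numpy())
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [pos.size - 1]))
        for i, j in zip(starts, ends):
            n_snp = j - i + 1
            span = int(pos[j] - pos[i])
            if n_snp < params.min_snp or span < params.min_length_bp:
                continue
            if span > 0 and n_snp / (span / 1000.0) < params.min_density_snp_per_kb:
                continue
            covered += span
    return covered / lengths.l_auto


def froh_fped_correlation(
    froh_by_sample: pd.DataFrame, fped_by_sample: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation between genomic and pedigree inbreeding.

    Both frames need ``sample_id`` plus ``froh_total`` / ``f_ped`` columns;
    samples are matched by id and at least 3 shared samples are required.
    Returns (r, two-sided p-value).
    """
    merged = froh_by_sample[["sample_id", "froh_total"]].merge(
        fped_by_sample[["sample_id", "f_ped"]], on="sample_id"
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 matched samples for a correlation")
    r, p = stats.pearsonr(merged["froh_total"], merged["f_ped"])
    return float(r), float(p)
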