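"""Sliding-window detection of runs of homozygosity (ROH).

The detector follows the classic sliding-window scheme for array data:

1. every contiguous block of ``window_size`` SNPs (stride 1) on a
   chromosome is scored homozygous iff it contains at most
   ``window_max_het`` heterozygous and ``window_max_miss`` missing calls;
2. each SNP receives the proportion of homozygous windows among the windows
   that cover it (fewer near chromosome ends — the denominator is the true
   covering count, no padding) and is flagged "in run" when that proportion
   exceeds ``snp_inrun_threshold``;
3. maximal stretches of flagged SNPs are split wherever two consecutive
   SNPs are more than ``max_gap_bp`` apart, and each resulting candidate is
   kept iff it has at least ``min_snp`` SNPs, spans at least
   ``min_length_bp`` (end - start), reaches ``min_density_snp_per_kb``, and
   contains at most ``run_max_het`` heterozygous / ``run_max_miss`` missing
   calls.

Run coordinates are the first and last SNP of the run (1-based), and run
length is ``end_bp - start_bp``.  With a window-level heterozygote
tolerance of zero the run-level allowance of one heterozygote is normally
vacuous (a het SNP is never flagged); it is still enforced as a post-filter
so that permissive window settings keep honest run statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_plink import MISSING, GenotypeMatrix

#: right edges (bp) of the five ROH length classes, in Mb: (0.1,1], (1,2],
#: (2,4], (4,8], (8,inf)
LENGTH_CLASS_EDGES_BP = (1_000_000, 2_000_000, 4_000_000, 8_000_000)
LENGTH_CLASS_LABELS = ("0.1-1", "1-2", "2-4", "4-8", ">8")

ROH_COLUMNS = [
    "sample_id", "chrom", "start_bp", "end_bp", "length_bp",
    "n_snp", "n_het", "n_miss", "length_class",
]


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH settings (defaults: 670K-array study settings)."""

    window_size: int = 10
    window_max_het: int = 0
    window_max_miss: int = 0
    snp_inrun_threshold: float = 0.05
    max_gap_bp: int = 100_000
    min_density_snp_per_kb: float = 0.05
    min_snp: int = 10
    min_length_bp: int = 100_000
    run_max_het: int = 1
    run_max_miss: int = 1

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.min_snp < 1 or self.min_length_bp <= 0:
            raise ValueError("window_size/min_snp/min_length_bp must be positive")
        if not 0.0 <= self.snp_inrun_threshold < 1.0:
            raise ValueError("snp_inrun_threshold must be in [0, 1)")
        if min(self.window_max_het, self.window_max_miss,
               self.run_max_het, self.run_max_miss, self.max_gap_bp) < 0:
            raise ValueError("counts and gaps must be non-negative")

    def with_min_length(self, min_length_bp: int) -> "ROHParams":
        return replace(self, min_length_bp=min_length_bp)


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of length-w windows along the last axis (stride 1)."""
    c = np.cumsum(x, axis=-1, dtype=np.int32)
    out = c[..., w - 1:].copy()
    out[..., 1:] -= c[..., :-w]
    return out


def window_homozygosity(calls: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean homozygosity per sliding window for one or many samples.

    ``calls`` is (n_snps,) or (n_samples, n_snps), position-ordered.  Returns
    one flag per window (n_snps - window_size + 1 windows; zero windows when
    the chromosome is shorter than the window).
    """
    calls = np.asarray(calls)
    w = params.window_size
    if calls.shape[-1] < w:
        return np.zeros(calls.shape[:-1] + (0,), dtype=bool)
    het = _window_sums(calls == 1, w)
    mis = _window_sums(calls == MISSING, w)
    return (het <= params.window_max_het) & (mis <= params.window_max_miss)


def snp_inrun_flags(
    window_flags: np.ndarray, n_snps: int, params: ROHParams
) -> np.ndarray:
    """Per-SNP in-run flags from window flags.

    SNP ``j`` is covered by windows ``max(0, j-w+1) .. min(j, n_windows-1)``;
    its proportion of homozygous covering windows must exceed
    ``snp_inrun_threshold``.  SNPs covered by zero windows are not flagged.
    """
    window_flags = np.asarray(window_flags)
    w = params.window_size
    n_win = window_flags.shape[-1]
    if n_win == 0:
        return np.zeros(window_flags.shape[:-1] + (n_snps,), dtype=bool)
    # covering-window index range per SNP
    lo = np.maximum(np.arange(n_snps) - w + 1, 0)
    hi = np.minimum(np.arange(n_snps), n_win - 1)
    cov = (hi - lo + 1).astype(np.float64)
    c = np.cumsum(window_flags, axis=-1, dtype=np.int32)
    hom = np.take(c, hi, axis=-1) - np.where(
        lo > 0, np.take(c, lo - 1, axis=-1), 0
    )
    return hom / cov > params.snp_inrun_threshold


def _candidate_segments(
    flags: np.ndarray, big_gap_after: np.ndarray
) -> list[tuple[int, int]]:
    """Maximal flagged index stretches, split at big gaps.

    ``big_gap_after[i]`` marks a > max_gap spacing between SNP i and i+1.
    Returns (start_idx, end_idx) inclusive pairs.
    """
    n = flags.size
    if n == 0:
        return []
    start_here = flags & np.concatenate(([True], ~flags[:-1] | big_gap_after))
    end_here = flags & np.concatenate((~flags[1:] | big_gap_after, [True]))
    return list(zip(np.flatnonzero(start_here), np.flatnonzero(end_here)))


def call_runs(
    snp_flags: np.ndarray,
    calls: np.ndarray,
    positions: np.ndarray,
    params: ROHParams,
) -> list[dict]:
    """Runs for one sample on one chromosome.

    Inputs are aligned per-SNP arrays; returns one dict per surviving run
    with keys start_bp, end_bp, length_bp, n_snp, n_het, n_miss.
    """
    snp_flags = np.asarray(snp_flags, dtype=bool)
    positions = np.asarray(positions, dtype=np.int64)
    calls = np.asarray(calls)
    big_gap = (
        np.diff(positions) > params.max_gap_bp
        if positions.size > 1
        else np.zeros(0, dtype=bool)
    )
    het_cum = np.concatenate(([0], np.cumsum(calls == 1)))
    mis_cum = np.concatenate(([0], np.cumsum(calls == MISSING)))
    runs: list[dict] = []
    for i, j in _candidate_segments(snp_flags, big_gap):
        n_snp = j - i + 1
        length = int(positions[j] - positions[i])
        if n_snp < params.min_snp or length < params.min_length_bp:
            continue
        if length > 0 and n_snp / (length / 1000.0) < params.min_density_snp_per_kb:
            continue
        n_het = int(het_cum[j + 1] - het_cum[i])
        n_mis = int(mis_cum[j + 1] - mis_cum[i])
        if n_het > params.run_max_het or n_mis > params.run_max_miss:
            continue
        runs.append(
            {
                "start_bp": int(positions[i]),
                "end_bp": int(positions[j]),
                "length_bp": length,
                "n_snp": n_snp,
                "n_het": n_het,
                "n_miss": n_mis,
            }
        )
    return runs


def classify_length(length_bp: np.ndarray | int) -> np.ndarray:
    """Map run lengths to the five classes, right-closed edges."""
    idx = np.searchsorted(
        np.asarray(LENGTH_CLASS_EDGES_BP), np.atleast_1d(length_bp), side="left"
    )
    return np.asarray(LENGTH_CLASS_LABELS)[idx]


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH for every sample on every autosome.

    Returns a frame with :data:`ROH_COLUMNS`, deterministic for a fixed
    input: rows ordered by sample (registry order), chromosome (declared
    order), start position.
    """
    if params is None:
        params = ROHParams()
    records: list[dict] = []
    sample_ids = g.sample_ids
    for chrom in g.autosomes:
        idx = g.chrom_indices(chrom)
        if idx.size == 0:
            continue
        positions = g.markers["pos_bp"].to_numpy()[idx]
        calls = g.calls[:, idx]
        wflags = window_homozygosity(calls, params)
        flags = snp_inrun_flags(wflags, idx.size, params)
        for s in range(g.n_samples):
            for run in call_runs(flags[s], calls[s], positions, params):
                run["sample_id"] = sample_ids[s]
                run["chrom"] = chrom
                records.append(run)
    df = pd.DataFrame(records, columns=[c for c in ROH_COLUMNS if c != "length_class"])
    if len(df):
        order = {c: i for i, c in enumerate(g.autosomes)}
        sorder = {sid: i for i, sid in enumerate(sample_ids)}
        df["length_class"] = classify_length(df["length_bp"].to_numpy())
        df = (
            df.assign(_s=df["sample_id"].map(sorder), _c=df["chrom"].map(order))
            .sort_values(["_s", "_c", "start_bp"], kind="stable")
            .drop(columns=["_s", "_c"])
            .reset_index(drop=True)
        )
    else:
        df["length_class"] = pd.Series(dtype=str)
    return df[ROH_COLUMNS]
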