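"""LD-decay effective population size (Ne) trajectory.

For unphased array genotypes, linkage disequilibrium between two markers is
measured as the composite r-squared: the squared Pearson correlation of
genotype dosage codes across samples with both calls present.  Pairs are
restricted to the same chromosome and a distance window, binned by physical
distance, and each pair's r2 is adjusted for finite sample size by
subtracting 1/(beta * n) (beta = 1 for unphased composite LD).

Each distance bin maps to a recombination fraction c through a pluggable
distance-to-recombination modifier, and to a time depth t = 1/(2c)
generations ago.  Ne for the bin follows the LD formula

    Ne = (1 / (4 c)) * (1 / E[r2_adj] - alpha)

with alpha the constant absorbing mutation (2.2 in the study settings, 1
for drift only).  Bins whose adjusted LD is non-positive, or whose Ne comes
out negative, are flagged and excluded from the reported trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_plink import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def _linear(d: np.ndarray) -> np.ndarray:
    return d


def _haldane(d: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def _kosambi(d: np.ndarray) -> np.ndarray:
    return 0.5 * np.tanh(2.0 * d)


def _sved_feldman(d: np.ndarray) -> np.ndarray:
    # effective recombination for the drift formula: map distance to the
    # Haldane fraction c, then correct per the Sved & Feldman two-locus
    # homozygosity approximation, whose drift LD is
    # E[r2] = (1-c)^2 / (2 N c (2-c)) = 1 / (4 N c*) with
    # c* = c (2-c) / (2 (1-c)^2).  c* -> d as d -> 0 and exceeds 1/2 for
    # loosely linked loci, where plain 1/(4Nc) understates recombination.
    c = _haldane(d)
    return c * (2.0 - c) / (2.0 * (1.0 - c) ** 2)


MODIFIERS = {
    "linear": _linear,
    "haldane": _haldane,
    "kosambi": _kosambi,
    "sved_feldman": _sved_feldman,
}


@dataclass(frozen=True)
class NeConfig:
    """Settings of the LD-Ne estimator (defaults: the 670K study settings)."""

    min_pair_dist_bp: int = 50_000
    max_pair_dist_bp: int = 40_000_000
    n_bins: int = 30
    alpha: float = 2.2
    recomb_rate_per_bp: float = 1.24e-8
    mapping_modifier: str = "sved_feldman"
    sample_size_beta: int = 1
    min_maf: float = 0.05
    birth_year_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.min_pair_dist_bp >= self.max_pair_dist_bp:
            raise ValueError("min_pair_dist_bp must be < max_pair_dist_bp")
        if self.alpha <= 0 or self.recomb_rate_per_bp <= 0:
            raise ValueError("alpha and recombination rate must be positive")
        if self.mapping_modifier not in MODIFIERS:
            raise ValueError(f"unknown modifier {self.mapping_modifier!r}")
        if self.sample_size_beta not in (1, 2):
            raise ValueError("sample_size_beta must be 1 or 2")


def filter_cohort(g: GenotypeMatrix, birth_year_range: tuple[int, int]) -> GenotypeMatrix:
    """Restrict to samples born within [lo, hi] (inclusive)."""
    if "birth_year" not in g.samples.columns:
        raise ValueError("sample registry has no birth_year column")
    lo, hi = birth_year_range
    years = pd.to_numeric(g.samples["birth_year"], errors="coerce")
    keep = np.flatnonzero(((years >= lo) & (years <= hi)).to_numpy())
    if keep.size == 0:
        raise ValueError(f"no samples born in [{lo}, {hi}]")
    return g.take_samples(keep)


def _pair_r2_block(
    x0: np.ndarray, m: np.ndarray, a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete r2 and joint sample count for columns a x columns b.

    ``x0`` is the zero-filled dosage matrix, ``m`` the non-missing mask.
    Returns (r2, n) of shape (len(a), len(b)); pairs with < 2 joint
    observations or zero variance get r2 = NaN.
    """
    xa, ma = x0[:, a], m[:, a]
    xb, mb = x0[:, b], m[:, b]
    n = ma.T @ mb
    sx = xa.T @ mb
    sy = ma.T @ xb
    sxx = (xa * xa).T @ mb
    syy = ma.T @ (xb * xb)
    sxy = xa.T @ xb
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2, n


def pairwise_r2(
    g: GenotypeMatrix, cfg: NeConfig, block: int = 512
) -> pd.DataFrame:
    """All intra-chromosomal marker pairs within the distance window.

    Returns a frame with columns ``dist_bp, r2, n`` (joint non-missing
    sample count per pair).  Pairs with fewer than two complete
    observations, or a monomorphic member, are skipped.
    """
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    ns: list[np.ndarray] = []
    for chrom in g.autosomes:
        idx = g.chrom_indices(chrom)
        if idx.size < 2:
            continue
        pos = g.markers["pos_bp"].to_numpy()[idx]
        x = g.calls[:, idx].astype(np.float64)
        m = (g.calls[:, idx] != MISSING).astype(np.float64)
        x0 = x * m
        for start in range(0, idx.size, block):
            a = np.arange(start, min(start + block, idx.size))
            # partners strictly to the right, within the distance window
            lo = np.searchsorted(pos, pos[a[0]] + cfg.min_pair_dist_bp, "left")
            hi = np.searchsorted(pos, pos[a[-1]] + cfg.max_pair_dist_bp, "right")
            if lo >= hi:
                continue
            b = np.arange(lo, hi)
            r2, n = _pair_r2_block(x0, m, a, b)
            d = pos[b][np.newaxis, :] - pos[a][:, np.newaxis]
            ok = (
                (d >= cfg.min_pair_dist_bp)
                & (d <= cfg.max_pair_dist_bp)
                & ~np.isnan(r2)
            )
            dists.append(d[ok].astype(np.int64))
            r2s.append(r2[ok])
            ns.append(n[ok].astype(np.int64))
    if not dists:
        return pd.DataFrame(columns=["dist_bp", "r2", "n"])
    return pd.DataFrame(
        {
            "dist_bp": np.concatenate(dists),
            "r2": np.concatenate(r2s),
            "n": np.concatenate(ns),
        }
    )


def bin_and_adjust(pairs: pd.DataFrame, cfg: NeConfig) -> pd.DataFrame:
    """Equal-width distance bins with sample-size-adjusted mean r2.

    Per pair, r2_adj = r2 - 1/(beta * n); per bin, means over pairs.  Empty
    bins are omitted with a log message.  Columns: ``bin_index,
    mean_dist_bp, mean_r2_adj, n_pairs``.
    """
    edges = np.linspace(cfg.min_pair_dist_bp, cfg.max_pair_dist_bp, cfg.n_bins + 1)
    d = pairs["dist_bp"].to_numpy()
    r2_adj = pairs["r2"].to_numpy() - 1.0 / (
        cfg.sample_size_beta * pairs["n"].to_numpy()
    )
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, cfg.n_bins - 1)
    rows = []
    for b in range(cfg.n_bins):
        sel = which == b
        if not sel.any():
            log.warning("distance bin %d is empty; omitted", b)
            continue
        rows.append(
            {
                "bin_index": b,
                "mean_dist_bp": float(d[sel].mean()),
                "mean_r2_adj": float(r2_adj[sel].mean()),
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["bin_index", "mean_dist_bp", "mean_r2_adj", "n_pairs"])


def dist_to_c(dist_bp: np.ndarray | float, cfg: NeConfig) -> np.ndarray:
    """Physical distance (bp) to recombination fraction via the configured
    modifier; distances are first scaled to Morgans by the recombination
    rate per bp."""
    d = np.asarray(dist_bp, dtype=np.float64) * cfg.recomb_rate_per_bp
    return MODIFIERS[cfg.mapping_modifier](d)


def ne_from_bins(bins: pd.DataFrame, cfg: NeConfig) -> pd.DataFrame:
    """Ne trajectory points from binned LD.

    For each bin: c from the bin's mean distance, t = 1/(2c) generations
    ago, Ne = (1/(4c)) (1/mean_r2_adj - alpha).  Bins with non-positive
    adjusted LD or negative Ne are excluded (logged).  Points are ordered
    newest (largest c) to oldest.
    """
    out = bins.copy()
    out["c"] = dist_to_c(out["mean_dist_bp"].to_numpy(), cfg)
    out["t_generations"] = 1.0 / (2.0 * out["c"])
    usable = out["mean_r2_adj"] > 0
    if (~usable).any():
        log.warning("%d bins dropped: non-positive adjusted r2", int((~usable).sum()))
    out = out[usable].copy()
    out["ne"] = (1.0 / (4.0 * out["c"])) * (1.0 / out["mean_r2_adj"] - cfg.alpha)
    neg = out["ne"] < 0
    if neg.any():
        log.warning("%d bins dropped: negative Ne (1/r2_adj < alpha)", int(neg.sum()))
    out = out[~neg]
    out = out.sort_values("c", ascending=False).reset_index(drop=True)
    return out[["bin_index", "mean_dist_bp", "c", "t_generations",
                "mean_r2_adj", "n_pairs", "ne"]]


def estimate_ne(g: GenotypeMatrix, cfg: NeConfig | None = None) -> pd.DataFrame:
    """Convenience pipeline: cohort filter -> pairwise r2 -> bins -> Ne."""
    if cfg is None:
        cfg = NeConfig()
    if cfg.birth_year_range is not None:
        g = filter_cohort(g, cfg.birth_year_range)
    pairs = pairwise_r2(g, cfg)
    if not len(pairs):
        raise ValueError("no usable marker pairs in the distance window")
    return ne_from_bins(bin_and_adjust(pairs, cfg), cfg)
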