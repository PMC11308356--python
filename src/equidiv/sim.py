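"""Synthetic array-like genotypes with known ground truth.

Two generators share one machinery:

* **gene dropping** — founder haplotypes are dropped through a pedigree
  with recombination; every haplotype carries a founder-copy label, so true
  autozygous (identical-by-descent) segments are known exactly.  This is
  the ground truth used to validate ROH detection and F_ROH.
* **Wright-Fisher** — a closed population of constant diploid size under
  random mating for a chosen number of generations, no mutation; the final
  generation is sampled.  Its census size is the true Ne used to validate
  the LD-based Ne estimator.

Recombination model: crossovers form a Poisson process along the
chromosome (no interference).  Restricted to the marker loci this is
equivalent to an independent-switch Markov chain between adjacent markers
with switch probability (1 - exp(-2 d r)) / 2 (Haldane), which is how
gametes are generated — exact in distribution at the markers and fully
vectorisable.  Truth segments are therefore recorded at marker resolution
(first to last marker with coinciding founder labels), matching the
resolution at which runs of homozygosity can be observed.

Missingness and genotyping error (a flip to a uniformly chosen different
code) are injected on the emitted genotypes only; the truth is recorded
beforehand and never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_plink import MISSING, GenotypeMatrix, IntervalRecord, export_bed, write_plink
from .pedigree import Pedigree

#: default per-bp recombination rate, matching the Ne-analysis assumption
DEFAULT_RECOMB_RATE = 1.24e-8


@dataclass(frozen=True)
class SimConfig:
    """Shape and noise of the simulated array dataset.

    The defaults emulate a desk-scale slice of a 670K-array autosomal
    dataset: 10 chromosomes of 17 Mb at 5,000 markers each reproduce the
    array's marker density (~0.29 SNP/kb); founder allele frequencies are
    uniform minor-allele frequencies on [0.05, 0.5], the ascertainment-
    biased spectrum typical of array content.
    """

    n_chromosomes: int = 10
    chromosome_length_bp: int = 17_000_000
    n_snps_per_chromosome: int = 5_000
    spacing: str = "uniform"  # or "jittered"
    freq_law: str = "uniform_maf"  # or "beta"
    beta_a: float = 2.0
    beta_b: float = 2.0
    maf_min: float = 0.05
    recomb_rate_per_bp: float = DEFAULT_RECOMB_RATE
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.genotype_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.spacing not in ("uniform", "jittered"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if self.freq_law not in ("uniform_maf", "beta"):
            raise ValueError(f"unknown freq_law {self.freq_law!r}")


@dataclass
class TruthSet:
    """Simulator ground truth.

    ``segments``: per-sample true autozygous intervals (marker-bounded,
    1-based inclusive, disjoint per sample and chromosome).
    ``autozygous_fraction``: per-sample summed segment length over the
    marker-covered genome length.  For Wright-Fisher output, ``true_ne``
    and ``n_generations`` record the simulated truth instead.
    """

    segments: pd.DataFrame
    autozygous_fraction: pd.Series
    pedigree: Pedigree | None = None
    true_ne: int | None = None
    n_generations: int | None = None


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        n = cfg.n_snps_per_chromosome
        if cfg.spacing == "uniform":
            pos = np.linspace(1, cfg.chromosome_length_bp, n).astype(np.int64)
        else:
            pos = np.sort(
                rng.choice(cfg.chromosome_length_bp, size=n, replace=False)
            ).astype(np.int64) + 1
        rows.append(
            pd.DataFrame(
                {
                    "chrom": str(c),
                    "snp_id": [f"snp_{c}_{i}" for i in range(n)],
                    "pos_bp": pos,
                    "allele_a": "A",
                    "allele_b": "B",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _founder_freqs(cfg: SimConfig, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.freq_law == "beta":
        return rng.beta(cfg.beta_a, cfg.beta_b, size=n_snps)
    maf = rng.uniform(cfg.maf_min, 0.5, size=n_snps)
    flip = rng.random(n_snps) < 0.5
    return np.where(flip, maf, 1.0 - maf)


def _switch_probs(markers: pd.DataFrame, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-adjacency haplotype-switch probability and chromosome-start mask.

    At a chromosome start the gamete picks a parental haplotype uniformly
    (probability 1/2); between adjacent markers d bp apart the Haldane
    switch probability is (1 - exp(-2 d r)) / 2.
    """
    pos = markers["pos_bp"].to_numpy()
    chrom = markers["chrom"].to_numpy()
    d = np.diff(pos, prepend=pos[:1])
    new_chrom = np.concatenate(([True], chrom[1:] != chrom[:-1]))
    p = 0.5 * (1.0 - np.exp(-2.0 * np.maximum(d, 0) * rate))
    p[new_chrom] = 0.5
    return p, new_chrom


def _gametes(
    haplos: np.ndarray,
    parent_rows: np.ndarray,
    switch_p: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Recombinant gametes for a batch of parents.

    ``haplos``: (2 * n_individuals, n_snps) haplotype array (alleles or
    founder labels — any dtype); ``parent_rows``: (G,) individual indices.
    Returns (gametes (G, n_snps), hap_indicator) — the indicator is reused
    to gather a second array (e.g. labels) through :func:`_gather`.
    """
    g = parent_rows.size
    s = switch_p.size
    switches = rng.random((g, s)) < switch_p[np.newaxis, :]
    ind = np.cumsum(switches, axis=1, dtype=np.int32) & 1
    return _gather(haplos, parent_rows, ind), ind


def _gather(haplos: np.ndarray, parent_rows: np.ndarray, ind: np.ndarray) -> np.ndarray:
    cols = np.arange(haplos.shape[1])
    return haplos[2 * parent_rows[:, np.newaxis] + ind, cols[np.newaxis, :]]


def simulate_founders(
    cfg: SimConfig, n_founders: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Founder haplotypes, founder-copy labels and the marker map.

    Returns ``(haplotypes (2F, S) int8, labels (2F, S) int32, markers)``;
    haplotype 2f/2f+1 belong to founder f and carry labels 2f/2f+1 at every
    marker, the handles by which identity-by-descent is tracked.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    n_snps = len(markers)
    p = _founder_freqs(cfg, n_snps, rng)
    haps = (rng.random((2 * n_founders, n_snps)) < p[np.newaxis, :]).astype(np.int8)
    labels = np.repeat(
        np.arange(2 * n_founders, dtype=np.int32)[:, np.newaxis], n_snps, axis=1
    )
    return haps, labels, markers


def _inject_noise(
    calls: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    calls = calls.copy()
    if cfg.genotype_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls[err] = (calls[err] + shift[err]) % 3
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING
    return calls


def _truth_from_labels(
    lab_mat: np.ndarray,
    lab_pat: np.ndarray,
    markers: pd.DataFrame,
    sample_ids: list[str],
) -> TruthSet:
    """Autozygous segments = maximal marker runs with equal founder labels."""
    pos = markers["pos_bp"].to_numpy()
    chroms = markers["chrom"].to_numpy()
    new_chrom = np.concatenate(([True], chroms[1:] != chroms[:-1]))
    rows = []
    genome_len = 0
    for c, grp in markers.groupby("chrom", sort=False):
        genome_len += int(grp["pos_bp"].max() - grp["pos_bp"].min())
    frac = np.zeros(len(sample_ids))
    for i, sid in enumerate(sample_ids):
        ibd = lab_mat[i] == lab_pat[i]
        # a segment starts where ibd and (first marker of chrom or prev not ibd)
        prev_ibd = np.concatenate(([False], ibd[:-1]))
        start_here = ibd & (~prev_ibd | new_chrom)
        next_ibd = np.concatenate((ibd[1:], [False]))
        next_new = np.concatenate((new_chrom[1:], [True]))
        end_here = ibd & (~next_ibd | next_new)
        total = 0
        for a, b in zip(np.flatnonzero(start_here), np.flatnonzero(end_here)):
            if pos[b] > pos[a]:
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": chroms[a],
                        "start_bp": int(pos[a]),
                        "end_bp": int(pos[b]),
                    }
                )
                total += int(pos[b] - pos[a])
        frac[i] = total / genome_len if genome_len else 0.0
    segments = pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp", "end_bp"])
    return TruthSet(
        segments=segments,
        autozygous_fraction=pd.Series(frac, index=sample_ids, name="autozygous_fraction"),
    )


def gene_drop(
    ped: Pedigree,
    cfg: SimConfig,
    target_ids: list[str] | None = None,
    population: str = "simpop",
) -> tuple[GenotypeMatrix, TruthSet]:
    """Drop founder haplotypes through ``ped`` with recombination.

    Pedigree founders (unknown-parent individuals) receive independent
    founder haplotypes; every other individual inherits one recombinant
    gamete from each parent.  Returns genotypes for ``target_ids``
    (default: all pedigree members) and the marker-resolution truth.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = ped.topological
    founders = [i for i in ids if ped.parents(i) == (None, None)]
    haps, labels, markers = simulate_founders(cfg, len(founders), rng)
    switch_p, _ = _switch_probs(markers, cfg.recomb_rate_per_bp)
    n_snps = len(markers)

    idx = {iid: k for k, iid in enumerate(ids)}
    all_h = np.zeros((2 * len(ids), n_snps), dtype=np.int8)
    all_l = np.zeros((2 * len(ids), n_snps), dtype=np.int32)
    for f_i, iid in enumerate(founders):
        k = idx[iid]
        all_h[2 * k : 2 * k + 2] = haps[2 * f_i : 2 * f_i + 2]
        all_l[2 * k : 2 * k + 2] = labels[2 * f_i : 2 * f_i + 2]
    for iid in ids:
        sire, dam = ped.parents(iid)
        if sire is None and dam is None:
            continue
        k = idx[iid]
        # pedigree is acyclic and iterated in topological order, so both
        # parents' haplotypes are already filled
        for slot, parent in enumerate((sire, dam)):
            prow = np.array([idx[parent]])
            gam, ind = _gametes(all_h, prow, switch_p, rng)
            all_h[2 * k + slot] = gam[0]
            all_l[2 * k + slot] = _gather(all_l, prow, ind)[0]

    if target_ids is None:
        target_ids = list(ids)
    rows = np.array([idx[i] for i in target_ids])
    lab_mat = all_l[2 * rows]
    lab_pat = all_l[2 * rows + 1]
    truth = _truth_from_labels(lab_mat, lab_pat, markers, list(target_ids))
    truth.pedigree = ped

    calls = (all_h[2 * rows] + all_h[2 * rows + 1]).astype(np.int8)
    calls = _inject_noise(calls, cfg, rng)
    samples = pd.DataFrame(
        {
            "sample_id": list(target_ids),
            "family_id": population,
            "population": population,
            "birth_year": [
                ped.birth_year.get(i, 0) for i in target_ids
            ],
        }
    )
    autosomes = tuple(str(c) for c in range(1, cfg.n_chromosomes + 1))
    g = GenotypeMatrix(samples, markers, calls, autosomes)
    return g, truth


def wright_fisher(
    cfg: SimConfig,
    n_diploid: int,
    n_generations: int,
    sample_size: int,
    population: str = "wf",
) -> tuple[GenotypeMatrix, TruthSet]:
    """Constant-size Wright-Fisher population; final-generation sample.

    Discrete non-overlapping generations, random mating with replacement
    (two parents drawn per offspring), recombination as in gene dropping,
    no mutation.  ``sample_size`` individuals from the last generation are
    emitted.
    """
    if n_diploid < 2:
        raise ValueError("need at least 2 diploid individuals")
    if sample_size > n_diploid:
        raise ValueError("sample_size cannot exceed the census size")
    rng = np.random.default_rng(cfg.seed)
    # founders of the initial generation are unrelated
    haps, _, markers = simulate_founders(cfg, n_diploid, rng)
    switch_p, _ = _switch_probs(markers, cfg.recomb_rate_per_bp)
    for _gen in range(n_generations):
        parents = rng.integers(0, n_diploid, size=2 * n_diploid)
        gam, _ind = _gametes(haps, parents, switch_p, rng)
        nxt = np.empty_like(haps)
        nxt[0::2] = gam[: n_diploid]
        nxt[1::2] = gam[n_diploid :]
        haps = nxt
    pick = rng.choice(n_diploid, size=sample_size, replace=False)
    calls = (haps[2 * pick] + haps[2 * pick + 1]).astype(np.int8)
    calls = _inject_noise(calls, cfg, rng)
    sample_ids = [f"{population}_{i}" for i in range(sample_size)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "family_id": population,
            "population": population,
            "birth_year": 0,
        }
    )
    autosomes = tuple(str(c) for c in range(1, cfg.n_chromosomes + 1))
    g = GenotypeMatrix(samples, markers, calls, autosomes)
    truth = TruthSet(
        segments=pd.DataFrame(columns=["sample_id", "chrom", "start_bp", "end_bp"]),
        autozygous_fraction=pd.Series(dtype=float),
        true_ne=n_diploid,
        n_generations=n_generations,
    )
    return g, truth


def emit(
    g: GenotypeMatrix, truth: TruthSet, out_prefix: str, dialect: str = "binary"
) -> None:
    """Write genotypes as PLINK files and the truth as TSV + BED.

    Sample metadata beyond the PLINK fam fields (population, birth year)
    goes into a ``.meta.tsv`` sidecar, re-attachable via
    :func:`equidiv.io_plink.read_plink`'s ``metadata`` argument.
    """
    write_plink(g, out_prefix, dialect=dialect)
    extra = [c for c in g.samples.columns if c not in ("sample_id", "family_id")]
    if extra:
        g.samples[["sample_id"] + extra].to_csv(
            f"{out_prefix}.meta.tsv", sep="\t", index=False
        )
    truth.segments.to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
    records = [
        IntervalRecord(r.chrom, r.start_bp, r.end_bp, name=r.sample_id)
        for r in truth.segments.itertuples(index=False)
        if r.start_bp < r.end_bp
    ]
    export_bed(records, f"{out_prefix}.truth.bed")


def plant_sweep(
    g: GenotypeMatrix,
    chrom: str,
    start_bp: int,
    end_bp: int,
    carrier_fraction: float,
    rng: np.random.Generator,
) -> list[str]:
    """Engineer a selection signature: make a random ``carrier_fraction``
    of samples homozygous (allele-a) across a marker interval, in place.

    Emulates a swept haplotype near fixation so that ROH-island calling
    has a region of known extent and carrier share to recover.  Returns
    the carrier sample ids.
    """
    on = (
        (g.markers["chrom"] == chrom)
        & g.markers["pos_bp"].between(start_bp, end_bp)
    ).to_numpy()
    carriers = rng.choice(
        g.n_samples, size=int(round(carrier_fraction * g.n_samples)), replace=False
    )
    g.calls[np.ix_(carriers, np.flatnonzero(on))] = 0
    return [g.sample_ids[i] for i in sorted(carriers)]


def random_mating_pedigree(
    n_founders: int,
    n_generations: int,
    n_per_generation: int,
    seed: int = 0,
    full_sib_fraction: float = 0.0,
) -> Pedigree:
    """A closed-population pedigree: each generation's individuals draw a
    sire from the previous generation's males and a dam from its females.

    ``full_sib_fraction`` forces that share of each generation to be
    produced by repeating the previous mating pair, creating full sibs and
    (after another generation) close-inbreeding loops — useful for cohorts
    with a wide spread of inbreeding.
    """
    rng = np.random.default_rng(seed)
    records: dict[str, tuple[str | None, str | None]] = {}
    birth: dict[str, int] = {}
    males = [f"G0_M{i}" for i in range(n_founders // 2)]
    females = [f"G0_F{i}" for i in range(n_founders - n_founders // 2)]
    for i in males + females:
        records[i] = (None, None)
        birth[i] = 0
    for t in range(1, n_generations + 1):
        new_m: list[str] = []
        new_f: list[str] = []
        last_pair: tuple[str, str] | None = None
        for j in range(n_per_generation):
            if last_pair is not None and rng.random() < full_sib_fraction:
                sire, dam = last_pair
            else:
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
                last_pair = (sire, dam)
            sex_m = rng.random() < 0.5
            iid = f"G{t}_{'M' if sex_m else 'F'}{j}"
            records[iid] = (sire, dam)
            birth[iid] = t
            (new_m if sex_m else new_f).append(iid)
        # guard against a single-sex generation in tiny populations
        if not new_m:
            new_m = males
        if not new_f:
            new_f = females
        males, females = new_m, new_f
    return Pedigree(records, birth)
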