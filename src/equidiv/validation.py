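"""Ground-truth validation harness.

Brute-force reference implementations (an exhaustive interval oracle for
ROH calling and Wright's path-counting method for pedigree kinship) and
the simulation-based recovery checks built on them.  Everything here is
deliberately written independently of the production code paths it
validates: the oracle enumerates every candidate interval in plain Python,
and the kinship oracle counts ancestor paths instead of running the
tabular recursion.

The high-level ``check_*`` functions regenerate their synthetic inputs
from a seed, run the production pipeline, and report recovery metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import expected_het, observed_het
from .io_plink import MISSING
from .ne_ld import NeConfig, estimate_ne
from .pedigree import KinshipCalculator
from .qc import QCConfig, apply_qc
from .roh import ROHParams, call_runs, detect_roh, snp_inrun_flags, window_homozygosity
from .roh_stats import GenomeLengths, call_islands, froh
from .sim import SimConfig, gene_drop, random_mating_pedigree, wright_fisher

# ---------------------------------------------------------------------------
# exhaustive ROH oracle
# ---------------------------------------------------------------------------


def oracle_window_flags(calls: list[int], params: ROHParams) -> list[bool]:
    w = params.window_size
    flags = []
    for a in range(len(calls) - w + 1):
        block = calls[a : a + w]
        n_het = sum(1 for c in block if c == 1)
        n_mis = sum(1 for c in block if c == MISSING)
        flags.append(
            n_het <= params.window_max_het and n_mis <= params.window_max_miss
        )
    return flags


def oracle_snp_flags(calls: list[int], params: ROHParams) -> list[bool]:
    w = params.window_size
    wflags = oracle_window_flags(calls, params)
    out = []
    for s in range(len(calls)):
        covering = [k for k in range(len(wflags)) if k <= s <= k + w - 1]
        if not covering:
            out.append(False)
            continue
        prop = sum(wflags[k] for k in covering) / len(covering)
        out.append(prop > params.snp_inrun_threshold)
    return out


def oracle_runs(
    calls: list[int], positions: list[int], params: ROHParams
) -> list[tuple[int, int]]:
    """All runs as (start_bp, end_bp) by exhaustive interval enumeration.

    An index interval [i, j] qualifies iff every SNP is flagged, it is
    maximal (bounded by an unflagged SNP, an over-limit gap, or the
    chromosome end), contains no internal over-limit gap, and passes the
    min-SNP / min-length / density / het / missing filters.
    """
    n = len(calls)
    flags = oracle_snp_flags(calls, params)
    found = []
    for i in range(n):
        for j in range(i, n):
            if not all(flags[k] for k in range(i, j + 1)):
                continue
            if any(
                positions[k + 1] - positions[k] > params.max_gap_bp
                for k in range(i, j)
            ):
                continue
            left_max = (
                i == 0
                or not flags[i - 1]
                or positions[i] - positions[i - 1] > params.max_gap_bp
            )
            right_max = (
                j == n - 1
                or not flags[j + 1]
                or positions[j + 1] - positions[j] > params.max_gap_bp
            )
            if not (left_max and right_max):
                continue
            n_snp = j - i + 1
            length = positions[j] - positions[i]
            if n_snp < params.min_snp or length < params.min_length_bp:
                continue
            if length > 0 and n_snp / (length / 1000.0) < params.min_density_snp_per_kb:
                continue
            n_het = sum(1 for k in range(i, j + 1) if calls[k] == 1)
            n_mis = sum(1 for k in range(i, j + 1) if calls[k] == MISSING)
            if n_het > params.run_max_het or n_mis > params.run_max_miss:
                continue
            found.append((positions[i], positions[j]))
    return found


# ---------------------------------------------------------------------------
# path-counting kinship oracle
# ---------------------------------------------------------------------------


def _paths_up(ped, iid: str) -> list[tuple[str, tuple[str, ...]]]:
    """All ancestor paths from ``iid`` upward, incl. the trivial path."""
    out = [(iid, (iid,))]
    sire, dam = ped.parents(iid)
    for p in (sire, dam):
        if p is not None:
            for anc, nodes in _paths_up(ped, p):
                out.append((anc, (iid,) + nodes))
    return out


def path_counting_kinship(ped, a: str, b: str, _memo=None) -> float:
    """f(a, b) = sum over common ancestors A and node-disjoint path pairs
    of (1/2)^(l1 + l2 + 1) (1 + F_A) — Wright's method."""
    if _memo is None:
        _memo = {}
    if a == b:
        return 0.5 * (1.0 + path_counting_inbreeding(ped, a, _memo))
    total = 0.0
    for anc_a, nodes_a in _paths_up(ped, a):
        set_a = set(nodes_a)
        for anc_b, nodes_b in _paths_up(ped, b):
            if anc_a != anc_b or set_a.intersection(nodes_b) != {anc_a}:
                continue
            f_anc = path_counting_inbreeding(ped, anc_a, _memo)
            total += 0.5 ** (len(nodes_a) + len(nodes_b) - 1) * (1.0 + f_anc)
    return total


def path_counting_inbreeding(ped, iid: str, _memo=None) -> float:
    if _memo is None:
        _memo = {}
    if iid in _memo:
        return _memo[iid]
    sire, dam = ped.parents(iid)
    if sire is None or dam is None:
        _memo[iid] = 0.0
        return 0.0
    f = path_counting_kinship(ped, sire, dam, _memo)
    _memo[iid] = f
    return f


# ---------------------------------------------------------------------------
# recovery checks (regenerate inputs -> run pipeline -> measure)
# ---------------------------------------------------------------------------

#: desk-scale ROH parameters used for the randomized oracle comparison —
#: small windows/limits so that <= 50-SNP instances exercise every filter
ORACLE_PARAMS = ROHParams(
    window_size=5,
    snp_inrun_threshold=0.05,
    max_gap_bp=100_000,
    min_density_snp_per_kb=0.05,
    min_snp=4,
    min_length_bp=50_000,
)


def random_roh_instance(rng: np.random.Generator, n_max: int = 50):
    n = int(rng.integers(5, n_max + 1))
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=n,
        p=[0.42, 0.08, 0.42, 0.08],
    )
    gaps = rng.choice(
        [5_000, 20_000, 60_000, 150_000], size=n - 1, p=[0.4, 0.4, 0.1, 0.1]
    )
    pos = np.concatenate([[1], 1 + np.cumsum(gaps)]).astype(np.int64)
    return calls, pos


def check_roh_oracle(seed: int, n_instances: int = 1000,
                     params: ROHParams = ORACLE_PARAMS) -> dict:
    """Fraction of random small instances on which the sliding-window
    detector reproduces the exhaustive oracle's run set exactly."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_instances):
        calls, pos = random_roh_instance(rng)
        wf = window_homozygosity(calls, params)
        flags = snp_inrun_flags(wf, calls.size, params)
        got = {
            (r["start_bp"], r["end_bp"])
            for r in call_runs(flags, calls, pos, params)
        }
        if got == set(oracle_runs(list(calls), list(pos), params)):
            matches += 1
    return {"agreement": matches / n_instances, "n": n_instances}


def _acceptance_cohort(seed: int, n_samples: int = 100):
    """A gene-dropped cohort with a wide spread of true autozygosity:
    4 generations over 40 founders with a 30% full-sib mating share,
    on a 10-chromosome genome at 670K-like marker density."""
    ped = random_mating_pedigree(
        40, 4, n_samples, seed=seed, full_sib_fraction=0.3
    )
    targets = [i for i in ped.topological if ped.birth_year.get(i) == 4]
    cfg = SimConfig(seed=seed)  # 10 x 17 Mb x 5000 SNPs, zero noise
    g, truth = gene_drop(ped, cfg, target_ids=targets)
    return g, truth


def _overlap_bp(intervals_a: np.ndarray, intervals_b: np.ndarray) -> int:
    """Total length of the intersection of two disjoint interval sets."""
    total = 0
    for s, e in intervals_a:
        lo = np.minimum(np.maximum(intervals_b[:, 0], s), e)
        hi = np.maximum(np.minimum(intervals_b[:, 1], e), s)
        total += int(np.maximum(hi - lo, 0).sum())
    return total


def check_froh_truth(seed: int, n_samples: int = 100) -> dict:
    """Gene-dropping recovery: correlation of F_ROH with the true
    autozygous fraction, base-pair recall of truth segments >= 1 Mb, and
    the share of detected ROH bp falling outside truth segments >= 100 kb."""
    g, truth = _acceptance_cohort(seed, n_samples)
    runs = detect_roh(g, ROHParams())
    lengths = GenomeLengths.from_marker_map(g.markers)
    table = froh(runs, g.sample_ids, lengths).set_index("sample_id")
    r, _ = stats.pearsonr(
        table["froh_total"], truth.autozygous_fraction.loc[table.index]
    )

    segs = truth.segments
    long_truth = segs[segs["end_bp"] - segs["start_bp"] >= 1_000_000]
    recall_num = recall_den = 0
    detect_outside = detect_total = 0
    for sid in g.sample_ids:
        r_s = runs[runs["sample_id"] == sid]
        t_s = segs[segs["sample_id"] == sid]
        lt_s = long_truth[long_truth["sample_id"] == sid]
        for chrom in g.autosomes:
            det = r_s[r_s["chrom"] == chrom][["start_bp", "end_bp"]].to_numpy()
            tru_long = lt_s[lt_s["chrom"] == chrom][["start_bp", "end_bp"]].to_numpy()
            tru_all = t_s[t_s["chrom"] == chrom]
            tru_100k = tru_all[
                tru_all["end_bp"] - tru_all["start_bp"] >= 100_000
            ][["start_bp", "end_bp"]].to_numpy()
            if tru_long.size:
                recall_den += int((tru_long[:, 1] - tru_long[:, 0]).sum())
                if det.size:
                    recall_num += _overlap_bp(tru_long, det)
            if det.size:
                d_total = int((det[:, 1] - det[:, 0]).sum())
                detect_total += d_total
                inside = _overlap_bp(det, tru_100k) if tru_100k.size else 0
                detect_outside += d_total - inside
    return {
        "pearson_r": float(r),
        "recall_bp": recall_num / recall_den if recall_den else float("nan"),
        "detected_outside_truth": (
            detect_outside / detect_total if detect_total else 0.0
        ),
        "n": len(g.sample_ids),
    }


def check_ne_recovery(seed: int, n_seeds: int = 10, true_ne: int = 100,
                      n_generations: int = 200, sample_size: int = 100) -> dict:
    """Recent-generation Ne recovered from Wright-Fisher data (the newest
    trajectory point), per replicate seed."""
    estimates = []
    for k in range(n_seeds):
        cfg = SimConfig(
            n_chromosomes=20,
            chromosome_length_bp=100_000_000,
            n_snps_per_chromosome=1_000,
            seed=(seed + 7919 * k) % (2**31),
        )
        g, _ = wright_fisher(cfg, true_ne, n_generations, sample_size)
        g, _ = apply_qc(g, QCConfig.profile("diversity"))
        traj = estimate_ne(g, NeConfig())
        estimates.append(float(traj["ne"].iloc[0]))
    hits = sum(
        1 for v in estimates if abs(v - true_ne) / true_ne <= 0.35
    )
    return {
        "estimates": estimates,
        "median": float(np.median(estimates)),
        "within_35pct": hits,
        "n": n_seeds,
        "true_ne": true_ne,
    }


def check_pedigree_exactness(seed: int, n_individuals: int = 100) -> dict:
    """Max |F_tabular - F_path-counting| over a random pedigree, plus the
    classic full-sib and half-sib offspring values."""
    from .pedigree import Pedigree, inbreeding

    ped = random_mating_pedigree(
        20, 4, (n_individuals - 20) // 4, seed=seed, full_sib_fraction=0.3
    )
    f_fast = inbreeding(ped).set_index("sample_id")["f_ped"]
    memo: dict = {}
    max_err = max(
        abs(f_fast[iid] - path_counting_inbreeding(ped, iid, memo))
        for iid in ped.topological
    )
    full_sib = Pedigree(
        {"gs": (None, None), "gd": (None, None),
         "s": ("gs", "gd"), "d": ("gs", "gd"), "x": ("s", "d")}
    )
    half_sib = Pedigree(
        {"gs": (None, None), "gd1": (None, None), "gd2": (None, None),
         "s": ("gs", "gd1"), "d": ("gs", "gd2"), "x": ("s", "d")}
    )
    calc_fs = KinshipCalculator(full_sib)
    calc_hs = KinshipCalculator(half_sib)
    return {
        "max_abs_error": float(max_err),
        "n": len(ped.topological),
        "full_sib_f": calc_fs.inbreeding("x"),
        "half_sib_f": calc_hs.inbreeding("x"),
    }


def check_island_construction(seed: int, n_random_tracks: int = 50) -> dict:
    """The engineered 25-SNP sweep at incidence 0.9 must come back as one
    island at the 0.70 threshold; random tracks must nest across thresholds."""
    values = [0.2] * 10 + [0.9] * 25 + [0.2] * 10
    inc = pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"m{i}" for i in range(len(values))],
            "pos_bp": 1 + 10_000 * np.arange(len(values)),
            "incidence": values,
        }
    )
    islands = call_islands(inc, 0.70)
    sweep_ok = (
        len(islands) == 1
        and islands[0].n_snp == 25
        and islands[0].start_bp == inc.loc[10, "pos_bp"]
        and islands[0].end_bp == inc.loc[34, "pos_bp"]
    )
    rng = np.random.default_rng(seed)
    nested = 0
    for _ in range(n_random_tracks):
        track = inc.copy()
        track["incidence"] = rng.uniform(0.0, 1.0, len(values))
        low = call_islands(track, 0.70)
        high = call_islands(track, 0.80)
        if all(
            any(
                l.start_bp <= h.start_bp and h.end_bp <= l.end_bp
                for l in low
            )
            for h in high
        ):
            nested += 1
    return {
        "sweep_recovered": bool(sweep_ok),
        "sweep_n_islands": len(islands),
        "nesting_ok_fraction": nested / n_random_tracks,
        "n": n_random_tracks,
    }


def check_het_consistency(seed: int, n_samples: int = 500,
                          n_snps: int = 5_000) -> dict:
    """Hardy-Weinberg cohort: |mean H_O - H_E| against 3 standard errors."""
    from .io_plink import GenotypeMatrix

    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.5, n_snps)
    calls = rng.binomial(2, p, size=(n_samples, n_snps)).astype(np.int8)
    markers = pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"m{i}" for i in range(n_snps)],
            "pos_bp": 1 + 3_000 * np.arange(n_snps),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n_samples)], "family_id": "hw"}
    )
    g = GenotypeMatrix(samples, markers, calls, ("1",))
    het = observed_het(g)
    cohort = expected_het(g)
    se = float(het["h_obs"].std(ddof=1) / np.sqrt(n_samples))
    diff = float(abs(het["h_obs"].mean() - cohort.mean_h_exp))
    return {
        "mean_h_obs": float(het["h_obs"].mean()),
        "mean_h_exp": cohort.mean_h_exp,
        "abs_diff": diff,
        "se": se,
        "abs_diff_over_se": diff / se,
        "n": n_samples,
    }
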