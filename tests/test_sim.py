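import numpy as np
import pandas as pd
import pytest

from equidiv.diversity import observed_het
from equidiv.io_plink import import_bed, read_plink
from equidiv.pedigree import Pedigree
from equidiv.sim import (
    SimConfig,
    emit,
    gene_drop,
    random_mating_pedigree,
    simulate_founders,
    wright_fisher,
)

SMALL = SimConfig(n_chromosomes=2, chromosome_length_bp=5_000_000,
                  n_snps_per_chromosome=500, seed=11)


def _sib_pedigree(n_offspring=1, prefix=""):
    rows = {f"{prefix}gs": (None, None), f"{prefix}gd": (None, None),
            f"{prefix}s": (f"{prefix}gs", f"{prefix}gd"),
            f"{prefix}d": (f"{prefix}gs", f"{prefix}gd")}
    for k in range(n_offspring):
        rows[f"{prefix}x{k}"] = (f"{prefix}s", f"{prefix}d")
    return Pedigree(dict(rows))


def test_simulate_founders_laws():
    cfg = SimConfig(n_chromosomes=1, n_snps_per_chromosome=10_000,
                    maf_min=0.5, seed=3)  # point mass at p = 0.5
    haps, labels, markers = simulate_founders(cfg, 50)
    freqs = haps.mean(axis=0)
    assert abs(freqs.mean() - 0.5) < 0.01
    assert labels.shape == haps.shape
    assert set(np.unique(labels[:, 0])) == set(range(100))

    cfg_b = SimConfig(n_chromosomes=1, n_snps_per_chromosome=10_000,
                      freq_law="beta", seed=3)
    haps_b, _, _ = simulate_founders(cfg_b, 100)
    p_hat = haps_b.mean(axis=0)
    # E[2p(1-p)] under Beta(2,2) = 0.4 (allowing binomial sampling shrinkage)
    assert abs(np.mean(2 * p_hat * (1 - p_hat)) - 0.4) < 0.02


def test_generators_deterministic_under_seed():
    g1, t1 = gene_drop(_sib_pedigree(), SMALL)
    g2, t2 = gene_drop(_sib_pedigree(), SMALL)
    np.testing.assert_array_equal(g1.calls, g2.calls)
    pd.testing.assert_frame_equal(t1.segments, t2.segments)
    w1, _ = wright_fisher(SMALL, 20, 5, 10)
    w2, _ = wright_fisher(SMALL, 20, 5, 10)
    np.testing.assert_array_equal(w1.calls, w2.calls)


def test_unrelated_parents_no_autozygosity():
    ped = Pedigree({"s": (None, None), "d": (None, None), "x": ("s", "d")})
    _, truth = gene_drop(ped, SMALL, target_ids=["x"])
    assert len(truth.segments) == 0
    assert truth.autozygous_fraction["x"] == 0.0


def test_full_sib_offspring_quarter_autozygous():
    """Offspring of full sibs are 25% autozygous in expectation."""
    ped = _sib_pedigree(n_offspring=300)
    cfg = SimConfig(n_chromosomes=4, chromosome_length_bp=20_000_000,
                    n_snps_per_chromosome=400, seed=21)
    _, truth = gene_drop(ped, cfg, target_ids=[f"x{k}" for k in range(300)])
    mean = truth.autozygous_fraction.mean()
    se = truth.autozygous_fraction.std(ddof=1) / np.sqrt(300)
    assert abs(mean - 0.25) < max(4 * se, 0.02)


def test_full_sib_line_inbreeding_recurrence():
    """Mean autozygosity of a full-sib mating chain follows the classical
    inbreeding recurrence F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4."""
    f = {0: 0.0, -1: 0.0}
    for t in range(1, 6):
        f[t] = 0.25 * (1 + 2 * f[t - 1] + f[t - 2])
    # 40 replicate lines, 5 generations of brother-sister mating
    rows = {}
    for line in range(40):
        rows[f"L{line}_M0"] = (None, None)
        rows[f"L{line}_F0"] = (None, None)
        for t in range(1, 6):
            for sex in ("M", "F"):
                rows[f"L{line}_{sex}{t}"] = (
                    f"L{line}_M{t-1}", f"L{line}_F{t-1}"
                )
    ped = Pedigree(rows)
    cfg = SimConfig(n_chromosomes=5, chromosome_length_bp=20_000_000,
                    n_snps_per_chromosome=300, seed=9)
    targets = [f"L{l}_{s}{t}" for l in range(40) for s in "MF" for t in (2, 3, 5)]
    _, truth = gene_drop(ped, cfg, target_ids=targets)
    means = {}
    for t in (2, 3, 5):
        # generation-t individuals are offspring of the (t-1)-th sib mating
        ids = [f"L{l}_{s}{t}" for l in range(40) for s in "MF"]
        means[t] = truth.autozygous_fraction[ids].mean()
        assert abs(means[t] - f[t - 1]) < 0.06
    assert means[2] < means[3] < means[5]


def test_truth_segments_disjoint_per_sample():
    ped = random_mating_pedigree(10, 4, 30, seed=2, full_sib_fraction=0.3)
    _, truth = gene_drop(ped, SMALL)
    for (sid, chrom), grp in truth.segments.groupby(["sample_id", "chrom"]):
        g = grp.sort_values("start_bp")
        assert (g["start_bp"].to_numpy()[1:] > g["end_bp"].to_numpy()[:-1]).all()
    assert ((truth.autozygous_fraction >= 0) & (truth.autozygous_fraction <= 1)).all()


def test_noise_injection_preserves_truth_and_shape():
    noisy = SimConfig(n_chromosomes=2, chromosome_length_bp=5_000_000,
                      n_snps_per_chromosome=500, seed=11,
                      missing_rate=0.05, genotype_error_rate=0.01)
    ped = _sib_pedigree(n_offspring=30)
    g_clean, t_clean = gene_drop(_sib_pedigree(n_offspring=30), SMALL)
    g_noisy, t_noisy = gene_drop(ped, noisy)
    from equidiv.io_plink import MISSING
    frac_missing = (g_noisy.calls == MISSING).mean()
    assert 0.03 < frac_missing < 0.07
    # same seed, same pedigree structure -> identical truth despite noise
    pd.testing.assert_frame_equal(t_clean.segments, t_noisy.segments)


def test_wright_fisher_drift_loses_heterozygosity():
    cfg = SimConfig(n_chromosomes=2, chromosome_length_bp=5_000_000,
                    n_snps_per_chromosome=300, maf_min=0.5, seed=4)
    g0, _ = wright_fisher(cfg, 2, 0, 2)
    g40, _ = wright_fisher(cfg, 2, 40, 2)
    h0 = observed_het(g0)["h_obs"].mean()
    h40 = observed_het(g40)["h_obs"].mean()
    assert h40 < h0 * 0.5


def test_wright_fisher_drift_variance():
    """Across-locus variance of allele frequency after t generations matches
    p(1-p)(1 - (1 - 1/2N)^t)."""
    n, t = 50, 20
    cfg = SimConfig(n_chromosomes=20, chromosome_length_bp=50_000_000,
                    n_snps_per_chromosome=100, maf_min=0.5, seed=8)
    g, _ = wright_fisher(cfg, n, t, n)
    p_hat = g.calls.mean(axis=0) / 2.0
    expect = 0.25 * (1 - (1 - 1 / (2 * n)) ** t)
    assert np.var(p_hat) == pytest.approx(expect, rel=0.25)


def test_emit_round_trip(tmp_path):
    ped = _sib_pedigree(n_offspring=5)
    g, truth = gene_drop(ped, SMALL, target_ids=[f"x{k}" for k in range(5)])
    emit(g, truth, str(tmp_path / "sim"))
    g2 = read_plink(tmp_path / "sim", autosomes=g.autosomes)
    np.testing.assert_array_equal(g.calls, g2.calls)
    back = pd.read_csv(tmp_path / "sim.truth.tsv", sep="\t",
                       dtype={"chrom": str})
    pd.testing.assert_frame_equal(
        back, truth.segments.reset_index(drop=True), check_dtype=False
    )
    bed = import_bed(tmp_path / "sim.truth.bed")
    assert len(bed) == len(truth.segments)
    for rec, row in zip(bed, truth.segments.itertuples(index=False)):
        assert (rec.chrom, rec.start_bp, rec.end_bp) == (
            row.chrom, row.start_bp, row.end_bp
        )
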