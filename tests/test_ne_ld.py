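import numpy as np
import pandas as pd
import pytest

from equidiv.io_plink import MISSING
from equidiv.ne_ld import (
    MODIFIERS,
    NeConfig,
    bin_and_adjust,
    dist_to_c,
    estimate_ne,
    filter_cohort,
    ne_from_bins,
    pairwise_r2,
)

from conftest import make_matrix

CFG = NeConfig(min_pair_dist_bp=10_000, max_pair_dist_bp=10_000_000, n_bins=5)


def test_pairwise_r2_hand_computed():
    """A 5-SNP fixture matches hand-computed composite correlations."""
    calls = np.array(
        [
            [0, 0, 2, 1, 0],
            [1, 1, 1, 1, 0],
            [2, 2, 0, 1, 0],
            [0, 0, 2, 0, 0],
            [2, 2, 0, 2, 0],
        ],
        dtype=np.int8,
    )
    pos = [100_000, 200_000, 300_000, 400_000, 500_000]
    g = make_matrix(calls, positions=pos)
    pairs = pairwise_r2(g, CFG)
    got = {
        (int(r.dist_bp)): r.r2 for r in pairs.itertuples()
    }
    # SNP0 vs SNP1 identical columns -> r2 = 1
    p01 = pairs[(pairs["dist_bp"] == 100_000)]
    by_hand = {}
    for i in range(5):
        for j in range(i + 1, 5):
            x, y = calls[:, i].astype(float), calls[:, j].astype(float)
            vx, vy = x.var(), y.var()
            if vx == 0 or vy == 0:
                continue
            r = ((x - x.mean()) * (y - y.mean())).mean() / np.sqrt(vx * vy)
            by_hand[(i, j)] = r * r
    # SNP4 monomorphic: 4 usable pairs at 100kb? pairs (0,1),(1,2),(2,3),(3,4)->(3,4) dropped
    assert len(pairs) == len(by_hand)
    for (i, j), expect in by_hand.items():
        d = (j - i) * 100_000
        match = pairs[(pairs["dist_bp"] == d)]
        assert any(np.isclose(v, expect, atol=1e-12) for v in match["r2"])
    assert np.isclose(by_hand[(0, 1)], 1.0)
    assert (pairs["n"] == 5).all()


def test_pairwise_r2_missing_pairwise_complete():
    calls = np.array([[0, 0], [1, 1], [2, 2], [MISSING, 0], [2, MISSING]],
                     dtype=np.int8)
    g = make_matrix(calls, positions=[10_000, 60_000])
    pairs = pairwise_r2(g, NeConfig(min_pair_dist_bp=10_000,
                                    max_pair_dist_bp=1_000_000))
    assert len(pairs) == 1
    assert pairs.loc[0, "n"] == 3  # only rows with both calls
    assert pairs.loc[0, "r2"] == pytest.approx(1.0)


def test_null_r2_near_one_over_n(rng):
    """Independent columns: mean composite r2 ~ 1/n."""
    n = 500
    calls = rng.binomial(2, 0.5, size=(n, 300)).astype(np.int8)
    g = make_matrix(calls, positions=(np.arange(300) + 1) * 100_000)
    pairs = pairwise_r2(g, NeConfig(min_pair_dist_bp=50_000,
                                    max_pair_dist_bp=40_000_000))
    assert pairs["r2"].mean() == pytest.approx(1.0 / n, rel=0.15)


def test_bin_and_adjust_arithmetic():
    cfg = NeConfig(min_pair_dist_bp=0 + 50_000, max_pair_dist_bp=1_050_000,
                   n_bins=2, sample_size_beta=1)
    pairs = pd.DataFrame(
        {"dist_bp": [100_000, 900_000], "r2": [0.05, 0.2], "n": [100, 100]}
    )
    bins = bin_and_adjust(pairs, cfg)
    assert len(bins) == 2
    assert bins.loc[0, "mean_r2_adj"] == pytest.approx(0.05 - 0.01)
    assert bins.loc[1, "mean_r2_adj"] == pytest.approx(0.2 - 0.01)
    assert bins.loc[0, "n_pairs"] == 1


def test_bin_counts_match_histogram(rng):
    cfg = NeConfig(min_pair_dist_bp=50_000, max_pair_dist_bp=10_050_000, n_bins=10)
    d = rng.integers(50_000, 10_050_001, size=5_000)
    pairs = pd.DataFrame({"dist_bp": d, "r2": 0.1, "n": 50})
    bins = bin_and_adjust(pairs, cfg)
    hist, _ = np.histogram(
        d, bins=np.linspace(50_000, 10_050_000, 11)
    )
    assert bins["n_pairs"].tolist() == [h for h in hist if h > 0]


def test_dist_to_c_forms():
    cfg = NeConfig(mapping_modifier="linear")
    assert dist_to_c(1_000_000, cfg) == pytest.approx(0.0124)
    d = np.array([1e-6, 1e-5, 1e-4])
    for name, fn in MODIFIERS.items():
        np.testing.assert_allclose(fn(d), d, rtol=1e-3,
                                   err_msg=f"{name} small-d limit")
    # all modifiers agree pairwise within 1% up to 5 cM
    grid = np.linspace(1e-4, 0.005, 50)
    vals = {name: fn(grid) for name, fn in MODIFIERS.items()}
    for a in vals:
        for b in vals:
            np.testing.assert_allclose(vals[a], vals[b], rtol=0.01)


def test_ne_formula_evaluation():
    cfg = NeConfig(alpha=2.2, mapping_modifier="linear",
                   recomb_rate_per_bp=1.24e-8)
    # choose distance so that c = 0.125 under the linear map
    dist = 0.125 / 1.24e-8
    bins = pd.DataFrame(
        {"bin_index": [0], "mean_dist_bp": [dist], "mean_r2_adj": [0.1],
         "n_pairs": [10]}
    )
    pts = ne_from_bins(bins, cfg)
    assert pts.loc[0, "ne"] == pytest.approx((1 / 0.5) * (10 - 2.2))  # 15.6
    assert pts.loc[0, "t_generations"] == pytest.approx(4.0)
    # r2_adj = 1/alpha is the Ne = 0 boundary
    bins2 = bins.assign(mean_r2_adj=1 / 2.2)
    assert ne_from_bins(bins2, cfg).loc[0, "ne"] == pytest.approx(0.0, abs=1e-9)


def test_ne_monotonicity_and_exclusions():
    cfg = NeConfig(alpha=2.2, mapping_modifier="linear")
    mk = lambda r2: ne_from_bins(
        pd.DataFrame({"bin_index": [0], "mean_dist_bp": [5_000_000],
                      "mean_r2_adj": [r2], "n_pairs": [1]}), cfg
    )
    assert mk(0.05).loc[0, "ne"] > mk(0.10).loc[0, "ne"]
    # negative Ne (1/r2 < alpha) excluded, not clamped
    assert len(mk(0.9)) == 0
    # non-positive adjusted r2 dropped
    assert len(mk(-0.01)) == 0


def test_trajectory_ordering_newest_first(rng):
    cfg = NeConfig(mapping_modifier="linear")
    bins = pd.DataFrame(
        {"bin_index": [0, 1, 2],
         "mean_dist_bp": [1e6, 5e6, 20e6],
         "mean_r2_adj": [0.3, 0.1, 0.05],
         "n_pairs": [5, 5, 5]}
    )
    pts = ne_from_bins(bins, cfg)
    assert pts["c"].is_monotonic_decreasing
    assert pts["t_generations"].is_monotonic_increasing


def test_filter_cohort_by_birth_year():
    g = make_matrix(np.zeros((4, 3), dtype=np.int8),
                    birth_year=[2005, 2006, 2016, 2017])
    sub = filter_cohort(g, (2006, 2016))
    assert sub.sample_ids == ["s1", "s2"]
    with pytest.raises(ValueError):
        filter_cohort(g, (1900, 1901))


def test_estimate_ne_deterministic(rng):
    calls = rng.binomial(2, rng.uniform(0.1, 0.5, 400),
                         size=(60, 400)).astype(np.int8)
    g = make_matrix(calls, positions=(np.arange(400) + 1) * 200_000)
    cfg = NeConfig(n_bins=8)
    t1 = estimate_ne(g, cfg)
    t2 = estimate_ne(g, cfg)
    pd.testing.assert_frame_equal(t1, t2)
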