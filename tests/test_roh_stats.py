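import numpy as np
import pandas as pd
import pytest

from equidiv.roh import ROHParams, classify_length, detect_roh
from equidiv.roh_stats import (
    GenomeLengths,
    call_islands,
    coverage_validation,
    descriptive_table,
    froh,
    froh_fped_correlation,
    island_incidence,
    overlap_islands,
)

from conftest import make_matrix


def _runs(rows):
    df = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_bp", "end_bp"]
    )
    df["length_bp"] = df["end_bp"] - df["start_bp"]
    df["n_snp"] = 10
    df["n_het"] = 0
    df["n_miss"] = 0
    df["length_class"] = classify_length(df["length_bp"].to_numpy()) if len(df) else ""
    return df


GL = GenomeLengths(per_chrom={"1": 2_281_000_000}, l_auto=2_281_000_000)


def test_froh_ratio_and_zero():
    runs = _runs([("a", "1", 1, 228_100_001)])  # 228.1 Mb on a 2281 Mb genome
    table = froh(runs, ["a", "b"], GL)
    assert table.set_index("sample_id").loc["a", "froh_total"] == pytest.approx(0.10)
    assert table.set_index("sample_id").loc["b", "froh_total"] == 0.0


def test_froh_classes_sum_to_total(rng):
    rows = []
    for s in range(20):
        for _ in range(rng.integers(0, 8)):
            start = int(rng.integers(1, 2_000_000_000))
            rows.append((f"s{s}", "1", start, start + int(rng.integers(150_000, 12_000_000))))
    runs = _runs(rows)
    table = froh(runs, [f"s{i}" for i in range(20)], GL)
    class_cols = [c for c in table.columns if c.startswith("froh_") and
                  c not in ("froh_total",) and not c.startswith("froh_chr_")]
    np.testing.assert_allclose(
        table[class_cols].sum(axis=1), table["froh_total"], rtol=1e-12
    )
    # brute-force cohort mean
    expect = runs["length_bp"].sum() / (20 * GL.l_auto)
    assert table["froh_total"].mean() == pytest.approx(expect)


def test_froh_unknown_chromosome_raises():
    runs = _runs([("a", "9", 1, 200_000)])
    with pytest.raises(ValueError, match="absent"):
        froh(runs, ["a"], GL)


def test_descriptive_table_single_run():
    runs = _runs([("a", "1", 1, 1_500_001)])
    t = descriptive_table(runs, n_samples=5).set_index("length_class")
    assert t.loc["1-2", "n_ind"] == 1
    assert t.loc["1-2", "n_roh"] == 1
    assert t.loc["1-2", "roh_pct"] == 100.0
    assert t.loc["1-2", "s_roh"] == 1.0
    assert t.loc["1-2", "l_roh_mb"] == pytest.approx(1.5)


def test_descriptive_table_matches_brute_force(rng):
    rows = []
    for s in range(15):
        for _ in range(rng.integers(1, 10)):
            start = int(rng.integers(1, 10**9))
            rows.append((f"s{s}", "1", start, start + int(rng.integers(100_000, 10**7))))
    runs = _runs(rows)
    t = descriptive_table(runs, 15).set_index("length_class")
    assert t["n_roh"].sum() == len(runs)
    assert t["roh_pct"].sum() == pytest.approx(100.0)
    for cls in t.index:
        sub = runs[runs["length_class"] == cls]
        assert t.loc[cls, "n_roh"] == len(sub)
        assert t.loc[cls, "n_ind"] == sub["sample_id"].nunique()


def test_incidence_brute_force(rng):
    n_s, n_m = 8, 50
    pos = np.sort(rng.choice(10**6, n_m, replace=False)) + 1
    g = make_matrix(np.zeros((n_s, n_m), dtype=np.int8), positions=pos)
    rows = []
    for s in range(n_s):
        cursor = 1
        for _ in range(rng.integers(0, 4)):
            start = cursor + int(rng.integers(0, 200_000))
            end = start + int(rng.integers(10_000, 300_000))
            rows.append((f"s{s}", "1", start, end))
            cursor = end + 1  # disjoint per sample
    runs = _runs(rows)
    inc = island_incidence(runs, g)["incidence"].to_numpy()
    for j, p in enumerate(pos):
        covered = {
            r.sample_id
            for r in runs.itertuples()
            if r.start_bp <= p <= r.end_bp
        }
        assert inc[j] == pytest.approx(len(covered) / n_s)


def test_incidence_trivial():
    g = make_matrix(np.zeros((4, 5), dtype=np.int8))
    inc = island_incidence(_runs([]), g)
    assert (inc["incidence"] == 0).all()
    inc = island_incidence(_runs([("s0", "1", 5_000, 45_000)]), g)
    assert inc["incidence"].tolist() == [0.25, 0.25, 0.25, 0.25, 0.0]


def _inc_frame(values, start=1, step=10_000):
    n = len(values)
    return pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"m{i}" for i in range(n)],
            "pos_bp": start + step * np.arange(n),
            "incidence": values,
        }
    )


def test_island_sweep_fixture():
    """A 25-SNP stretch at incidence 0.9 flanked by 0.2 gives one island."""
    inc = _inc_frame([0.2] * 10 + [0.9] * 25 + [0.2] * 10)
    islands = call_islands(inc, threshold=0.70)
    assert len(islands) == 1
    isl = islands[0]
    assert isl.n_snp == 25
    assert isl.start_bp == inc.loc[10, "pos_bp"]
    assert isl.end_bp == inc.loc[34, "pos_bp"]
    assert isl.peak_incidence == pytest.approx(0.9)


def test_island_threshold_strict_and_nesting(rng):
    values = rng.uniform(0.3, 1.0, 200)
    inc = _inc_frame(values)
    assert call_islands(_inc_frame([0.5] * 30), 0.70) == []
    # incidence exactly at threshold is NOT an island (strict >)
    assert call_islands(_inc_frame([0.70] * 30), 0.70) == []
    low = call_islands(inc, 0.70)
    high = call_islands(inc, 0.80)
    for h in high:
        assert any(
            l.chrom == h.chrom and l.start_bp <= h.start_bp and h.end_bp <= l.end_bp
            for l in low
        )


def test_overlap_islands_arithmetic():
    from equidiv.roh_stats import RohIsland

    def isl(chrom, s, e):
        return RohIsland(chrom, s, e, (e - s) / 1e3, 10, 0.9, 0.7)

    assert overlap_islands([isl("1", 100, 200)], [isl("2", 100, 200)]).empty
    df = overlap_islands([isl("1", 100, 200)], [isl("1", 150, 300)])
    assert df.loc[0, "shared_start_bp"] == 150
    assert df.loc[0, "shared_end_bp"] == 200
    # printed island pair: overlap length equals the end/start difference
    df = overlap_islands(
        [isl("17", 18_706_560, 18_829_942)], [isl("17", 18_735_602, 18_829_942)]
    )
    assert df.loc[0, "overlap_bp"] == 94_340


def test_coverage_validation_cases():
    params = ROHParams()
    # uniform 20 kb spacing: every constraint satisfiable -> full coverage
    m = pd.DataFrame({"chrom": "1", "snp_id": "x",
                      "pos_bp": 1 + 20_000 * np.arange(10_000)})
    assert coverage_validation(m, params) == pytest.approx(1.0)
    # a single 200 kb gap splits the map; both halves remain detectable, and
    # the gap's span is lost
    pos = np.concatenate([1 + 20_000 * np.arange(100),
                          2_180_001 + 20_000 * np.arange(100)])
    m2 = pd.DataFrame({"chrom": "1", "snp_id": "x", "pos_bp": pos})
    span = pos[-1] - pos[0]
    detectable = (pos[99] - pos[0]) + (pos[-1] - pos[100])
    assert coverage_validation(m2, params) == pytest.approx(detectable / span)
    # everywhere sparser than the density limit -> zero coverage
    m3 = pd.DataFrame({"chrom": "1", "snp_id": "x",
                       "pos_bp": 1 + 90_000 * np.arange(1_000)})
    assert coverage_validation(m3, params) == 0.0


def test_froh_fped_correlation_exact(rng):
    ids = [f"s{i}" for i in range(50)]
    f = rng.uniform(0, 0.3, 50)
    a = pd.DataFrame({"sample_id": ids, "froh_total": f})
    b = pd.DataFrame({"sample_id": ids, "f_ped": f})
    r, p = froh_fped_correlation(a, b)
    assert r == pytest.approx(1.0)
    b2 = pd.DataFrame({"sample_id": ids, "f_ped": -f})
    r2, _ = froh_fped_correlation(a, b2)
    assert r2 == pytest.approx(-1.0)
    # textbook formula comparison
    noise = f + rng.normal(0, 0.05, 50)
    b3 = pd.DataFrame({"sample_id": ids, "f_ped": noise})
    r3, _ = froh_fped_correlation(a, b3)
    x, y = f - f.mean(), noise - noise.mean()
    expect = (x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum())
    assert r3 == pytest.approx(expect, abs=1e-12)


def test_min_length_sensitivity_reduces_froh(rng):
    """F_ROH at a 500 kb minimum never exceeds F_ROH at 100 kb."""
    calls = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=(10, 3000),
                       p=[0.48, 0.04, 0.48])
    calls[:, 500:1000] = 0
    g = make_matrix(calls, positions=(np.arange(3000) + 1) * 3_000)
    gl = GenomeLengths.from_marker_map(g.markers)
    f100 = froh(detect_roh(g, ROHParams()), g.sample_ids, gl)
    f500 = froh(detect_roh(g, ROHParams(min_length_bp=500_000)), g.sample_ids, gl)
    assert (f500["froh_total"] <= f100["froh_total"] + 1e-15).all()
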