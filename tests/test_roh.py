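import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equidiv.io_plink import MISSING
from equidiv.roh import (
    ROHParams,
    call_runs,
    classify_length,
    detect_roh,
    snp_inrun_flags,
    window_homozygosity,
)

from conftest import make_matrix
from equidiv.validation import oracle_runs, oracle_snp_flags

SMALL = ROHParams(
    window_size=5,
    snp_inrun_threshold=0.05,
    max_gap_bp=100_000,
    min_density_snp_per_kb=0.05,
    min_snp=4,
    min_length_bp=50_000,
)


def test_window_flags_basic():
    p = ROHParams()
    hom10 = np.zeros(10, dtype=np.int8)
    flags = window_homozygosity(hom10, p)
    assert flags.shape == (1,) and flags[0]
    with_het = hom10.copy()
    with_het[4] = 1
    assert not window_homozygosity(with_het, p)[0]
    assert window_homozygosity(np.zeros(9, dtype=np.int8), p).shape == (0,)


def test_window_and_snp_flags_15_snp_fixture():
    """15 homozygous SNPs with a het at index 7: exactly the 6 windows not
    covering index 7 are homozygous, and the het SNP is never flagged."""
    p = ROHParams()  # window 10
    calls = np.zeros(15, dtype=np.int8)
    calls[7] = 1
    wf = window_homozygosity(calls, p)
    assert wf.shape == (6,)
    # windows start at 0..5; a window starting at a covers [a, a+9]
    expected = [not (a <= 7 <= a + 9) for a in range(6)]
    assert list(wf) == expected  # all False here: every window covers 7
    assert not any(expected)
    flags = snp_inrun_flags(wf, 15, p)
    assert not flags[7]
    assert not flags.any()  # all windows cover the het


def test_snp_flags_edge_coverage():
    """First SNP is covered by exactly one window; its flag follows it."""
    p = ROHParams(window_size=3, snp_inrun_threshold=0.05)
    calls = np.zeros(6, dtype=np.int8)
    wf = window_homozygosity(calls, p)
    flags = snp_inrun_flags(wf, 6, p)
    assert flags[0] == wf[0]
    assert flags.all()
    # matches oracle coverage arithmetic
    assert list(flags) == oracle_snp_flags(list(calls), p)


def test_call_runs_length_filter():
    """20 flagged SNPs spanning 50 kb fail a 100 kb minimum length."""
    p = ROHParams(min_snp=10, min_length_bp=100_000)
    pos = np.linspace(1, 50_000, 20).astype(np.int64)
    calls = np.zeros(20, dtype=np.int8)
    assert call_runs(np.ones(20, bool), calls, pos, p) == []


def test_call_runs_gap_split():
    """An internal 150 kb gap splits a candidate in two."""
    p = ROHParams(min_snp=10, min_length_bp=100_000, max_gap_bp=100_000,
                  min_density_snp_per_kb=0.05)
    pos1 = np.linspace(1, 200_000, 100)
    pos2 = np.linspace(350_000, 550_000, 100)
    pos = np.concatenate([pos1, pos2]).astype(np.int64)
    runs = call_runs(np.ones(200, bool), np.zeros(200, np.int8), pos, p)
    assert len(runs) == 2
    assert runs[0]["end_bp"] == 200_000 and runs[1]["start_bp"] == 350_000


def test_detect_roh_trivial_cases():
    het = np.ones((1, 300), dtype=np.int8)
    g = make_matrix(het, positions=(np.arange(300) + 1) * 20_000)
    assert len(detect_roh(g, ROHParams())) == 0

    hom = np.zeros((1, 300), dtype=np.int8)
    g = make_matrix(hom, positions=(np.arange(300) + 1) * 20_000)
    runs = detect_roh(g, ROHParams())
    assert len(runs) == 1
    assert runs.loc[0, "start_bp"] == 20_000
    assert runs.loc[0, "end_bp"] == 300 * 20_000


def test_length_class_boundaries():
    assert list(classify_length([1_000_000, 1_500_000, 2_000_000,
                                 8_000_000, 8_000_001])) == \
        ["0.1-1", "1-2", "1-2", "4-8", ">8"]


def _random_instance(rng, n_max=50):
    n = int(rng.integers(5, n_max + 1))
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8), size=n,
        p=[0.42, 0.08, 0.42, 0.08],
    )
    gaps = rng.choice([5_000, 20_000, 60_000, 150_000], size=n - 1,
                      p=[0.4, 0.4, 0.1, 0.1])
    pos = np.concatenate([[1], 1 + np.cumsum(gaps)]).astype(np.int64)
    return calls, pos


def _runs_as_set(runs):
    return {(r["start_bp"], r["end_bp"]) for r in runs}


def test_oracle_equivalence_random_instances(rng):
    """Detector equals the exhaustive interval oracle on random instances."""
    p = SMALL
    for _ in range(300):
        calls, pos = _random_instance(rng)
        wf = window_homozygosity(calls, p)
        flags = snp_inrun_flags(wf, calls.size, p)
        got = _runs_as_set(call_runs(flags, calls, pos, p))
        assert got == set(oracle_runs(list(calls), list(pos), p))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    data=st.lists(st.integers(0, 3), min_size=5, max_size=40),
    seed=st.integers(0, 10_000),
    wmax_het=st.integers(0, 1),
    thresh=st.sampled_from([0.0, 0.05, 0.5]),
)
def test_oracle_equivalence_property(data, seed, wmax_het, thresh):
    """Property form of the oracle equivalence, with varied parameters."""
    rng = np.random.default_rng(seed)
    calls = np.array([c if c < 3 else MISSING for c in data], dtype=np.int8)
    gaps = rng.choice([5_000, 40_000, 150_000], size=calls.size - 1)
    pos = np.concatenate([[1], 1 + np.cumsum(gaps)]).astype(np.int64)
    p = ROHParams(window_size=4, window_max_het=wmax_het,
                  snp_inrun_threshold=thresh, max_gap_bp=100_000,
                  min_density_snp_per_kb=0.05, min_snp=3, min_length_bp=30_000)
    wf = window_homozygosity(calls, p)
    flags = snp_inrun_flags(wf, calls.size, p)
    got = _runs_as_set(call_runs(flags, calls, pos, p))
    assert got == set(oracle_runs(list(calls), list(pos), p))


def test_min_length_monotonicity(rng):
    """Raising min_length or min_snp only removes runs, never adds."""
    calls = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=(20, 2000),
                       p=[0.48, 0.04, 0.48])
    calls[:, :800] = 0  # a long autozygous block
    g = make_matrix(calls, positions=(np.arange(2000) + 1) * 3_000)
    loose = detect_roh(g, ROHParams())
    strict = detect_roh(g, ROHParams(min_length_bp=500_000))
    assert len(strict) <= len(loose)
    loose_set = set(map(tuple, loose[["sample_id", "start_bp", "end_bp"]].values))
    strict_set = set(map(tuple, strict[["sample_id", "start_bp", "end_bp"]].values))
    assert strict_set <= loose_set


def test_detect_roh_deterministic(rng):
    calls = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=(5, 1000),
                       p=[0.49, 0.02, 0.49])
    g = make_matrix(calls, positions=(np.arange(1000) + 1) * 3_000)
    r1 = detect_roh(g, ROHParams())
    r2 = detect_roh(g, ROHParams())
    assert r1.equals(r2)


def test_runs_never_exceed_het_allowance(rng):
    """Reported runs respect the one-heterozygote run-level cap."""
    calls = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=(10, 3000),
                       p=[0.47, 0.06, 0.47])
    g = make_matrix(calls, positions=(np.arange(3000) + 1) * 3_000)
    runs = detect_roh(g, ROHParams())
    assert (runs["n_het"] <= 1).all() and (runs["n_miss"] <= 1).all()


def test_params_validation():
    with pytest.raises(ValueError):
        ROHParams(window_size=0)
    with pytest.raises(ValueError):
        ROHParams(snp_inrun_threshold=1.0)
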