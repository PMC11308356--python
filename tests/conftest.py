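import numpy as np
import pandas as pd
import pytest

from equidiv.io_plink import GenotypeMatrix


def make_matrix(
    calls,
    positions=None,
    chroms=None,
    sample_ids=None,
    autosomes=None,
    **sample_cols,
):
    """Hand-build a GenotypeMatrix from a nested list / array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_m = calls.shape
    if positions is None:
        positions = (np.arange(n_m) + 1) * 10_000
    if chroms is None:
        chroms = ["1"] * n_m
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_s)]
    if autosomes is None:
        autosomes = tuple(dict.fromkeys(chroms))
    markers = pd.DataFrame(
        {
            "chrom": chroms,
            "snp_id": [f"m{i}" for i in range(n_m)],
            "pos_bp": np.asarray(positions, dtype=np.int64),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "family_id": "fam"})
    for k, v in sample_cols.items():
        samples[k] = v
    return GenotypeMatrix(samples, markers, calls, tuple(autosomes))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
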