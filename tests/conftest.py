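import numpy as np
import pandas as pd
import pytest

from rohpop.io import GenotypeMatrix


def make_gm(calls, pos=None, chrom=None, samples=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a dosage array (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100_000
    if chrom is None:
        chrom = np.ones(m, int)
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(m)],
            "chrom": np.asarray(chrom, int),
            "pos_bp": np.asarray(pos, int),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples=list(samples), markers=markers, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


def random_gm(rng, n=20, m=50, missing_rate=0.0, chrom=None, pos=None) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        calls[rng.random((n, m)) < missing_rate] = -1
    return make_gm(calls, pos=pos, chrom=chrom)
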