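import logging

import numpy as np
import pandas as pd
import pytest

from triplemr.io import ExpressionData, GenotypeMatrix

logging.getLogger("triplemr").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_gm(dosages, chrom="1", pos=None, sample_ids=None):
    """Small GenotypeMatrix helper; dosages is samples x variants."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos if pos is not None else 1000 * (np.arange(m) + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    ids = sample_ids or [f"S{i}" for i in range(n)]
    return GenotypeMatrix(dosages, variants, ids)


def make_ed(counts, chrom="1", starts=None, length=1000, sample_ids=None):
    counts = np.asarray(counts)
    g, n = counts.shape
    starts = starts if starts is not None else 1 + 10_000 * np.arange(g)
    genes = pd.DataFrame(
        {
            "id": [f"g{i}" for i in range(g)],
            "chrom": chrom,
            "start": starts,
            "end": np.asarray(starts) + length,
        }
    )
    ids = sample_ids or [f"S{i}" for i in range(n)]
    return ExpressionData(counts, genes, ids)
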