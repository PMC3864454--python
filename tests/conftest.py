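import numpy as np
import pytest

from trapcycle.io_tables import CountMatrix, SampleMeta
import pandas as pd


@pytest.fixture
def design_times():
    """The 12 sampling times of the two-day design: CT0..20 on days 1 and 2."""
    return np.array([0, 4, 8, 12, 16, 20, 24, 28, 32, 36, 40, 44], dtype=float)


@pytest.fixture
def design_meta():
    """24-sample sheet: 6 CTs x 2 days x 2 replicates."""
    metas = []
    for rep in ("A", "B"):
        for day in (1, 2):
            for ct in (0.0, 4.0, 8.0, 12.0, 16.0, 20.0):
                metas.append(
                    SampleMeta(
                        sample_id=f"d{day}_ct{ct:g}_r{rep}", ct=ct, day=day, replicate=rep
                    )
                )
    return metas


@pytest.fixture
def small_counts(design_meta):
    """Deterministic 5-gene raw matrix over the 24-sample design."""
    rng = np.random.default_rng(42)
    vals = rng.integers(0, 500, size=(5, len(design_meta)))
    df = pd.DataFrame(
        vals,
        index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
        columns=[m.sample_id for m in design_meta],
    )
    return CountMatrix(values=df.astype(float), normalized=False)
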