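import numpy as np
import pandas as pd
import pytest

from translate_rank.polysome_rank import CountMatrix, FRACTIONS


def make_count_matrix(counts_by_group, n_replicates=4, genes=None):
    """Build a CountMatrix from {(condition, fraction): per-gene counts}.

    Every replicate of a group receives the same count vector, which keeps
    saturated-model expectations exact.
    """
    conditions = sorted({c for c, _ in counts_by_group})
    n_genes = len(next(iter(counts_by_group.values())))
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cols, data, meta = [], [], []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for frac in FRACTIONS:
                cols.append(f"{cond}_r{rep}_{frac}")
                data.append(np.asarray(counts_by_group[(cond, frac)]))
                meta.append((cond, rep, frac))
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    samples = pd.DataFrame(meta, index=cols,
                           columns=["condition", "replicate", "fraction"])
    return CountMatrix(counts=counts.astype(np.int64), samples=samples)


@pytest.fixture
def unit_size_factors():
    def _make(cm):
        return pd.Series(1.0, index=cm.counts.columns)
    return _make
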