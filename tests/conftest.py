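import numpy as np
import pandas as pd
import pytest

from degrank import DEGTable


def make_deg_table(
    label="cmp",
    gene_ids=("g1", "g2", "g3"),
    log2fc=(1.0, -0.5, 2.0),
    mean_expr=(100.0, 50.0, 30.0),
    p_value=(0.01, 0.2, 0.04),
    p_adj=None,
    symbols=None,
):
    n = len(gene_ids)
    return DEGTable(
        label,
        pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "symbol": list(symbols) if symbols is not None else list(gene_ids),
                "log2fc": list(log2fc),
                "mean_expr": list(mean_expr),
                "p_value": list(p_value),
                "p_adj": list(p_adj) if p_adj is not None else [np.nan] * n,
            }
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def deg_table():
    return make_deg_table()
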