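import numpy as np
import pandas as pd
import pytest

from haplomix.catalog import Catalog, GENE_COLUMNS


def make_catalog(p_trunc, p_syn=None, o_ptv=None, o_syn=None, included=None):
    """Build a small catalog from plain sequences."""
    p_trunc = np.asarray(p_trunc, dtype=float)
    n = len(p_trunc)
    p_syn = np.asarray(p_syn, dtype=float) if p_syn is not None else 3 * p_trunc
    o_ptv = np.asarray(o_ptv, dtype=int) if o_ptv is not None else np.zeros(n, int)
    o_syn = np.asarray(o_syn, dtype=int) if o_syn is not None else np.zeros(n, int)
    included = (
        np.asarray(included, dtype=bool) if included is not None else np.ones(n, bool)
    )
    df = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n)],
            "p_trunc": p_trunc,
            "p_syn": p_syn,
            "o_ptv": o_ptv,
            "o_ptv_severe": np.zeros(n, int),
            "o_syn": o_syn,
            "o_any": o_ptv + o_syn,
            "included": included,
        },
        columns=GENE_COLUMNS,
    )
    return Catalog(df, provenance=["test fixture"])


@pytest.fixture
def three_gene_catalog():
    """Relative truncation rates q = (0.5, 0.3, 0.2)."""
    return make_catalog([0.5, 0.3, 0.2])


@pytest.fixture
def rate_table_tsv(tmp_path):
    path = tmp_path / "rates.tsv"
    path.write_text(
        "gene\tp_syn\tp_stop\tp_frameshift\n"
        "g1\t1e-5\t2e-6\t3e-6\n"
        "g2\t2e-5\t1e-6\t1e-6\n"
    )
    return path
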