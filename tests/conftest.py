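import numpy as np
import pandas as pd
import pytest

from bsaqtl import MarkerTable


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def build_table(rows, bulks=("H", "L"), n_replicates=1):
    """Rows of (chrom, pos, a1, a2, *counts) in canonical count order."""
    from bsaqtl.io_map import count_columns

    cols = ["chrom", "pos", "allele_p1", "allele_p2"] + count_columns(
        bulks, n_replicates
    )
    df = pd.DataFrame(rows, columns=cols)
    return MarkerTable(df, tuple(bulks), n_replicates).sort().validate()


@pytest.fixture
def two_bulk_table():
    return build_table(
        [
            ("chrI", 100, "A", "G", 30, 10, 9, 31),
            ("chrI", 700, "C", "T", 22, 18, 20, 20),
            ("chrII", 50, "A", "T", 15, 25, 26, 14),
        ]
    )
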