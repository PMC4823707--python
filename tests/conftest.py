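import numpy as np
import pandas as pd
import pytest

from seqnoise import CountMatrix


@pytest.fixture
def two_group_matrix() -> CountMatrix:
    """3 genes x 6 samples, two groups of technical triplicates."""
    data = pd.DataFrame(
        {
            "a1": [2.0, 100.0, 7.0],
            "a2": [4.0, 90.0, 7.0],
            "a3": [6.0, 110.0, 7.0],
            "b1": [3.0, 210.0, 7.0],
            "b2": [5.0, 190.0, 7.0],
            "b3": [4.0, 200.0, 7.0],
        },
        index=["miR-1", "miR-21", "miR-flat"],
    )
    groups = {s: ("A" if s.startswith("a") else "B") for s in data.columns}
    return CountMatrix(data, groups)


@pytest.fixture
def counts_tsv(tmp_path):
    """A small count table + group sidecar on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene_id\ts1\ts2\ts3\n"
        "miR-1\t0\t1\t2\n"
        "miR-2\t3\t4\t5\n"
    )
    groups = tmp_path / "groups.tsv"
    groups.write_text("s1\tA\ns2\tA\ns3\tB\n")
    return counts, groups


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240401)
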