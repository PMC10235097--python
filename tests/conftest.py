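import numpy as np
import pandas as pd
import pytest

from methylthermo import MethylomeSample
from methylthermo.io import SITE_COLUMNS


def make_sample(sample_id, rows, group=""):
    """rows: iterable of (chrom, pos, n_meth, n_unmeth)."""
    df = pd.DataFrame(
        [(c, p, "+", "CG", m, u) for c, p, m, u in rows],
        columns=SITE_COLUMNS,
    )
    return MethylomeSample(sample_id, df, group_label=group)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pair():
    """Two 3-site samples sharing all keys, hand-set counts."""
    a = make_sample("a", [("chr1", 10, 4, 6), ("chr1", 20, 0, 10), ("chr2", 5, 9, 1)])
    b = make_sample("b", [("chr1", 10, 5, 5), ("chr1", 20, 8, 2), ("chr2", 5, 9, 1)])
    return a, b


@pytest.fixture
def cov_file(tmp_path):
    """A well-formed 5-line Bismark coverage file."""
    lines = [
        "chr1\t10\t10\t40.0\t4\t6",
        "chr1\t25\t25\t0.0\t0\t12",
        "chr1\t31\t31\t100.0\t7\t0",
        "chr2\t5\t5\t50.0\t5\t5",
        "chr2\t90\t90\t25.0\t1\t3",
    ]
    path = tmp_path / "toy.cov"
    path.write_text("\n".join(lines) + "\n")
    return path
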