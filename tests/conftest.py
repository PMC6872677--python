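import numpy as np
import pandas as pd
import pytest

from intertidal.io import OtuTable, tree_from_newick

WORKED_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def worked_tree():
    """3-tip tree with hand-computable path sums and PD values."""
    return tree_from_newick(WORKED_NEWICK)


@pytest.fixture
def toy_table():
    return OtuTable(pd.DataFrame(
        [[5, 0, 3], [2, 2, 2], [0, 7, 1]],
        index=["s1", "s2", "s3"], columns=["A", "B", "C"]))


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "habitat": ["water", "water", "sediment"],
            "size_fraction": ["micro", "nano", "none"],
            "season": ["spring", "spring", "summer"],
            "latitude": [24.5, 24.51, 24.52],
            "longitude": [118.1, 118.2, 118.3],
            "salinity": [25.0, 26.0, 28.0],
            "pH": [8.1, 8.0, 7.9],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"))


def random_table(rng: np.random.Generator, n_samples=4, n_taxa=6,
                 max_count=20) -> OtuTable:
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa))
    counts[:, 0] += 1  # keep every sample non-empty
    return OtuTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)]))


def naive_bmntd(x, y, D, weighted):
    """Independent double-loop oracle for betaMNTD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ix = [i for i in range(len(x)) if x[i] > 0]
    iy = [j for j in range(len(y)) if y[j] > 0]
    fx = [x[i] / x.sum() if weighted else 1 / len(ix) for i in ix]
    fy = [y[j] / y.sum() if weighted else 1 / len(iy) for j in iy]
    a = sum(f * min(D[i][j] for j in iy) for f, i in zip(fx, ix))
    b = sum(f * min(D[j][i] for i in ix) for f, j in zip(fy, iy))
    return 0.5 * (a + b)
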