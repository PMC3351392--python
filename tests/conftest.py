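import numpy as np
import pandas as pd
import pytest

from paxms.baits import bait_panel
from paxms.identifications import CountMatrix


@pytest.fixture
def panel():
    """The packaged six-peptide proline-motif bait panel."""
    return {b.id: b for b in bait_panel()}


@pytest.fixture
def small_raw_matrix():
    """3 proteins x 2 baits x 2 replicates of raw spectral counts."""
    cols = pd.MultiIndex.from_tuples(
        [("A", 1), ("A", 2), ("B", 1), ("B", 2)], names=["bait", "replicate"]
    )
    data = pd.DataFrame(
        [[5.0, 4.0, 0.0, 0.0], [5.0, 6.0, 0.0, 1.0], [0.0, 0.0, 10.0, 9.0]],
        index=pd.Index(["p1", "p2", "p3"], name="protein"),
        columns=cols,
    )
    return CountMatrix(data, "raw")


def random_count_matrix(rng: np.random.Generator, n_proteins=None, n_baits=None,
                        replicates=2) -> CountMatrix:
    """A random raw count matrix with at least one positive count per column."""
    n_proteins = n_proteins or int(rng.integers(2, 8))
    n_baits = n_baits or int(rng.integers(1, 4))
    cols = pd.MultiIndex.from_tuples(
        [(f"b{i}", r) for i in range(n_baits) for r in range(1, replicates + 1)],
        names=["bait", "replicate"],
    )
    vals = rng.poisson(3.0, size=(n_proteins, len(cols))).astype(float)
    vals[rng.integers(n_proteins), :] += 1  # keep every column total nonzero
    df = pd.DataFrame(vals, index=pd.Index([f"p{i}" for i in range(n_proteins)], name="protein"),
                      columns=cols)
    return CountMatrix(df, "raw")
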