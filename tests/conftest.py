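import numpy as np
import pandas as pd
import pytest

import retroregulon as rr


@pytest.fixture(scope="session")
def small_genome():
    """1 Mb single-chromosome genome with two TE families and 110 genes."""
    spec = rr.GenomeSpec(
        n_chroms=1,
        chrom_len=1_000_000,
        families={"LTR12": (2, 100, 500), "MER41": (2, 100, 500)},
        n_genes=100,
        n_kznf=10,
    )
    return rr.make_genome(spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        rng.poisson(50, size=(20, 8)).astype(float),
        index=[f"f{i:02d}" for i in range(20)],
        columns=[f"s{i}" for i in range(8)],
    )
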