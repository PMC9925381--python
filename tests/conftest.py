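import numpy as np
import pandas as pd
import pytest

import chicdyn as cd


@pytest.fixture(scope="session")
def two_type_corpus():
    """Two cell types with disjoint enriched regions; easy topic separation."""
    cfg = cd.SimConfig(n_region=300, n_type=2, n_cell_per_type=60,
                       frac_dynamic=0.3, fold_spec=[1.0, 8.0],
                       depth_median=3e3, seed=1)
    truth = cd.simulate_profiles(cfg)
    mat, labels = cd.simulate_cells(truth, cfg)
    return cfg, truth, mat, labels


@pytest.fixture(scope="session")
def two_type_topic_fit(two_type_corpus):
    _, _, mat, _ = two_type_corpus
    return cd.fit_topics(mat, K=2, seed=0)


@pytest.fixture
def small_cuts():
    """Hand-sized cut table on two chromosomes."""
    df = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
        "pos": [10, 50_000, 99_999, 5, 60_000, 119_999],
        "cell": ["a", "a", "b", "b", "a", "b"],
        "count": [1, 2, 1, 1, 3, 1],
    })
    return cd.CutTable(df)


@pytest.fixture
def small_bins():
    return cd.make_bins({"chr1": 120_000, "chr2": 120_000}, 50_000)


@pytest.fixture(scope="session")
def mixture_reference():
    """8 active x 4 repressive well-separated cluster profiles."""
    rng = np.random.default_rng(2)
    p = rng.dirichlet(np.ones(200) * 0.5, size=8)
    q = rng.dirichlet(np.ones(200) * 0.5, size=4)
    feats = [f"f{i}" for i in range(200)]
    ref = cd.build_reference(
        pd.DataFrame(np.round(p * 1e6), index=[f"c{i}" for i in range(8)], columns=feats),
        pd.DataFrame(np.round(q * 1e6), index=[f"l{i}" for i in range(4)], columns=feats),
    )
    return p, q, ref
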