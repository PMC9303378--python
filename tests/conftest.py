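import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dietsweep as ds

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def small_table():
    """4 taxa x 3 samples with metadata and taxonomy."""
    counts = np.array(
        [[90, 10, 0],
         [6, 40, 0],
         [4, 30, 7],
         [0, 20, 0]]
    )
    meta = pd.DataFrame(
        {"species": ["bison", "bison", "bighorn"],
         "season": ["summer", "winter", "summer"]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    tax = pd.DataFrame(
        {"family": ["Poaceae", "Poaceae", "Asteraceae", np.nan],
         "genus": ["PoaG01", np.nan, np.nan, np.nan],
         "species": [np.nan, np.nan, np.nan, np.nan]},
        index=pd.Index(["t1", "t2", "t3", "t4"], name="taxon_id"),
    )
    return ds.ReadCountTable(
        taxon_ids=["t1", "t2", "t3", "t4"],
        sample_ids=["s1", "s2", "s3"],
        counts=counts,
        sample_meta=meta,
        taxonomy=tax,
    )


@pytest.fixture(scope="session")
def wildlife():
    """Default synthetic wildlife dataset, shared across tests."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ds.generate_wildlife_dataset()


def random_tables(n_tables, n_taxa=10, n_samples=4, seed=0, max_count=200):
    """Random integer count tables for brute-force comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_tables):
        counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
        counts[rng.random(counts.shape) < 0.3] = 0
        out.append(ds.ReadCountTable(
            taxon_ids=[f"t{k}" for k in range(n_taxa)],
            sample_ids=[f"s{k}" for k in range(n_samples)],
            counts=counts,
        ))
    return out
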