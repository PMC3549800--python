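import numpy as np
import pandas as pd
import pytest

import tshrinkplus as tp


@pytest.fixture
def small_cm() -> tp.CountMatrix:
    """3 genes x 4 samples, 2-vs-2 design, hand-checkable values."""
    counts = pd.DataFrame(
        {
            "s1": [4, 0, 7],
            "s2": [6, 2, 7],
            "s3": [10, 1, 7],
            "s4": [14, 3, 7],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    cond = pd.Series({"s1": "1", "s2": "1", "s3": "2", "s4": "2"})
    return tp.CountMatrix(counts, cond)


@pytest.fixture(scope="session")
def null_dataset() -> tp.SimulatedDataset:
    """Mid-sized null NB dataset reused across read-only tests."""
    cfg = tp.SimulationConfig(genes=1000, n1=4, n2=4, de_fraction=0.0, seed=11)
    return tp.simulate_counts(cfg)


@pytest.fixture(scope="session")
def de_dataset() -> tp.SimulatedDataset:
    """Dataset with DE genes and a 6-vs-6 pool for subsampling tests."""
    cfg = tp.SimulationConfig(genes=1500, n1=6, n2=6, de_fraction=0.1, seed=23)
    return tp.simulate_counts(cfg)


@pytest.fixture(scope="session")
def de_covariate(de_dataset) -> pd.Series:
    track = tp.simulate_external_track(de_dataset, rho=0.8, m_replicates=6, seed=29)
    return tp.standardize_external(track, de_dataset.cm.gene_ids)
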