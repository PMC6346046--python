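import numpy as np
import pandas as pd
import pytest

from purkinet import simulate, normalize


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the default design (5 x 3, 1000 genes)."""
    cfg = simulate.SimConfig(seed=5)
    truth = simulate.generate_truth(cfg)
    cm, design = simulate.generate_counts(truth)
    return cfg, truth, cm, design


@pytest.fixture(scope="session")
def standardized_expression(default_study):
    from purkinet import network

    _, _, cm, design = default_study
    sf = normalize.estimate_size_factors(cm)
    vst = normalize.variance_stabilize(cm, sf)
    return normalize.standardize_rows(network.prefilter_genes(vst)), design


@pytest.fixture
def tiny_counts():
    """3 genes x 4 samples (2 time points x 2 replicates), hand-made."""
    from purkinet.io import CountMatrix, SampleDesign

    cm = CountMatrix(pd.DataFrame(
        [[10, 12, 40, 44], [5, 6, 5, 6], [100, 90, 110, 95]],
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3", "s4"],
        dtype=float,
    ))
    design = SampleDesign(pd.DataFrame(
        {"time_point": ["T0", "T0", "T1", "T1"], "time_rank": [0, 0, 1, 1],
         "replicate": [1, 2, 1, 2]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    ))
    return cm, design
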