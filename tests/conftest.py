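"""Shared fixtures: small expression datasets and one default synthetic run."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from eppid.data_io import ExpressionDataset, InteractionNetwork
from eppid.pipeline import RunConfig, analyze
from eppid.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture
def small_expression():
    """3 genes x 4 samples with one missing cell."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.5, np.nan, 1.5, 2.5], [2.0, 1.0, 0.0, -1.0]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionDataset(dataset_id="small", values=values)


@pytest.fixture
def path_network():
    """A - B - C path."""
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def default_scenario():
    """One reference synthetic scenario (seed fixed for the session)."""
    cfg = ScenarioConfig(seed=424242)
    return cfg, generate_scenario(cfg)


@pytest.fixture(scope="session")
def default_run(default_scenario):
    """Full pipeline results on the reference scenario."""
    cfg, (net, datasets, attributes, truth) = default_scenario
    results = analyze(net, datasets, attributes, RunConfig(seed=7))
    return net, datasets, attributes, truth, results
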