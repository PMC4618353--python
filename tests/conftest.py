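import warnings

import numpy as np
import pandas as pd
import pytest

from blastocomp import (
    ExpressionNormalizer,
    filter_expressed,
    log_transform,
)
from blastocomp.simulate import SimulationConfig, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_bundle():
    """Compact synthetic dataset for fast stage-level tests."""
    return simulate_dataset(SimulationConfig(n_genes=800), seed=7)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size synthetic dataset at generator defaults."""
    return simulate_dataset(SimulationConfig(), seed=42)


def _prepare(bundle):
    norm = ExpressionNormalizer().fit_transform(bundle.matrix, annotation=bundle.annotation)
    expressed = filter_expressed(norm, bundle.samples)
    norm = norm.subset_genes(expressed)
    return {
        "bundle": bundle,
        "normalized": norm,
        "log": log_transform(norm),
        "expressed": expressed,
        "elements": bundle.annotation.set_index("orthogroup_id")["muller_element"],
        "species": sorted(bundle.samples["species"].unique()),
    }


@pytest.fixture(scope="session")
def small_prepared(small_bundle):
    return _prepare(small_bundle)


@pytest.fixture(scope="session")
def default_prepared(default_bundle):
    return _prepare(default_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
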