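import warnings

import numpy as np
import pytest

from cellallometry import (
    AllometryDataset,
    ModelSpec,
    SamplerConfig,
    fisher_like_profile,
    generate_dataset,
    sample_posterior,
)

# arviz emits a refactor FutureWarning on import; irrelevant to the suite
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def fisher_dataset():
    """60-organism synthetic dataset from the diminishing-returns truth."""
    return generate_dataset(fisher_like_profile(seed=3))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Five hand-built observations spanning bacteria to large metazoans."""
    return AllometryDataset(
        N=np.array([1e1, 1e3, 1e6, 1e9, 1e13]),
        K=np.array([2.0, 4.0, 9.0, 30.0, 120.0]),
        labels=["a", "b", "c", "d", "e"],
    )


@pytest.fixture(scope="session")
def fast_config():
    """Reduced sampler budget used throughout the suite."""
    return SamplerConfig(chains=2, tune=800, draws=4000, seed=7)


@pytest.fixture(scope="session")
def dr_fit(fisher_dataset, fast_config):
    """A converged diminishing-returns/constant-sd fit, shared across tests."""
    fit = sample_posterior(
        fisher_dataset, ModelSpec("diminishing_returns", "constant"), fast_config
    )
    assert fit.converged, fit.diagnostics_note
    return fit
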