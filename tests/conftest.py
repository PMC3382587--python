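import numpy as np
import pytest

from ovamir.pipeline import run_pipeline
from ovamir.simulate import SyntheticConfig, generate_all


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def bundle20k():
    """The default synthetic study at 20k reads (shared, read-only)."""
    return generate_all(SyntheticConfig(seed=1, library_depth=20_000))


@pytest.fixture(scope="session")
def pipeline_result(bundle20k):
    """End-to-end pipeline run on the shared study (read-only)."""
    return run_pipeline(bundle=bundle20k)
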