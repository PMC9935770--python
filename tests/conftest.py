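import numpy as np
import pytest

from bilistrip import pipeline


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """One shared synthetic strip-image set (3 lamps x 12 concentrations)."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = pipeline.make_fixtures(out, seed=7)
    return manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
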