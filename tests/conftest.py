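import numpy as np
import pytest

from emseg.synthetic import SynthConfig, generate_sample, scheme_for


@pytest.fixture(scope="session")
def phantom_samples():
    """30 small deterministic phantoms shared across tests."""
    cfg = SynthConfig()
    return [generate_sample(cfg, seed=i) for i in range(30)]


@pytest.fixture(scope="session")
def scheme3():
    return scheme_for(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """A 10-phantom dataset written to disk with its manifest."""
    from emseg.synthetic import generate_dataset
    out = tmp_path_factory.mktemp("phantoms")
    manifest = generate_dataset(SynthConfig(), n=10, seed=7, out_dir=out)
    return manifest, out
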