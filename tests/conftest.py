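import numpy as np
import pytest

from cypet import synthetic as syn


@pytest.fixture(scope="session")
def toy_pair():
    return syn.make_toy_redox_pair(seed=0)


@pytest.fixture(scope="session")
def membrane_system():
    return syn.make_membrane_system(alpha=25.0, beta=90.0, tilt=40.0,
                                    axial_offset=30.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    from cypet.pipeline import write_demo_fixtures

    out = tmp_path_factory.mktemp("demo")
    write_demo_fixtures(out, seed=0, n_trajectories=2)
    return out
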