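import numpy as np
import pytest

from oximescreen import chem_enum, energy_rank


@pytest.fixture(scope="session")
def registry():
    return chem_enum.SubstituentRegistry.default()


@pytest.fixture(scope="session")
def table1():
    return energy_rank.load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pose_set(tmp_path_factory):
    """20 synthetic poses, 7 apical by construction, plus the truth table."""
    from oximescreen import synthetic_data

    out = tmp_path_factory.mktemp("poses")
    paths, truth = synthetic_data.make_pose_set(20, 7, seed=99, out_dir=out)
    return paths, truth
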