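import numpy as np
import pytest

from relrna import ConformerGroup, ModelConfig, make_hairpin
from relrna.model import RelationalDesignNet, group_tensors

# small widths keep forward/backward passes fast in unit tests
TINY = dict(node_scalar=16, node_vector=4, edge_scalar=8, edge_vector=1)


@pytest.fixture(scope="session")
def hairpin():
    """10-nt hairpin: 3-bp stem + 4-nt loop."""
    st, bp = make_hairpin(3, 4, seed=1)
    return st, bp


@pytest.fixture(scope="session")
def hairpin_group(hairpin):
    st, bp = hairpin
    return ConformerGroup(sequence=st.sequence, structures=[(st, bp)])


@pytest.fixture()
def tiny_config():
    return ModelConfig(num_layers=2, decoder="nar", seed=7, **TINY)


@pytest.fixture()
def tiny_net(tiny_config):
    return RelationalDesignNet(tiny_config)


@pytest.fixture()
def hairpin_tensors(hairpin_group, tiny_config):
    return group_tensors(hairpin_group, tiny_config)


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=seed).as_matrix()
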