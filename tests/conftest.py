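import pytest

from npevo import SimConfig, simulate_family_set
from npevo.synthetic_data import to_precursors


@pytest.fixture(scope="session")
def ccap_simulation():
    """A small default-condition CCAP family set with ground truth."""
    cfg = SimConfig(seed=20240917, family_id="CCAP", n_groups=6, taxa_per_group=4)
    seqset, truth = simulate_family_set(cfg)
    return cfg, seqset, truth


@pytest.fixture(scope="session")
def ccap_precursors(ccap_simulation):
    _, seqset, _ = ccap_simulation
    return to_precursors(seqset)
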