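import pytest

from hcmnet import example_network


@pytest.fixture
def fixture_net():
    """The 11-node / 16-edge worked-example network."""
    return example_network()


#: Hop-distance block of the worked example (rows v1..v10 as published;
#: the v11 row is filled by symmetry because its printed form contradicts
#: the symmetric entries of rows v5-v7).
FIXTURE_DISTANCES = {
    "v1": [0, 1, 1, 2, 3, 3, 2, 1, 1, 2, 2],
    "v2": [1, 0, 1, 2, 3, 2, 1, 2, 2, 3, 3],
    "v3": [1, 1, 0, 1, 2, 2, 2, 2, 2, 3, 3],
    "v4": [2, 2, 1, 0, 1, 1, 1, 3, 3, 4, 4],
    "v5": [3, 3, 2, 1, 0, 2, 2, 4, 4, 5, 5],
    "v6": [3, 2, 2, 1, 2, 0, 1, 4, 4, 5, 5],
    "v7": [2, 1, 2, 1, 2, 1, 0, 3, 3, 4, 4],
    "v8": [1, 2, 2, 3, 4, 4, 3, 0, 1, 2, 1],
    "v9": [1, 2, 2, 3, 4, 4, 3, 1, 0, 1, 1],
    "v10": [2, 3, 3, 4, 5, 5, 4, 2, 1, 0, 1],
    "v11": [2, 3, 3, 4, 5, 5, 4, 1, 1, 1, 0],
}
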