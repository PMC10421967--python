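import logging

import numpy as np
import pytest

from ncoinfer import Genome, MarkerMap, Tract

logging.getLogger("ncoinfer.em").setLevel(logging.ERROR)


@pytest.fixture
def tiny_genome() -> Genome:
    return Genome({"chr1": 100})


@pytest.fixture
def tiny_markers() -> MarkerMap:
    return MarkerMap({"P1": {"chr1": np.array([20, 40, 50, 52])}})


@pytest.fixture
def tiny_tract() -> Tract:
    return Tract("t1", "P1", "chr1", (50, 52))
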