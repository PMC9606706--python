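import numpy as np
import pytest

from pacsim.forward import compute_leadfield
from pacsim.geometry import (
    make_source_space,
    make_template_head,
    make_template_montage,
)


@pytest.fixture(scope="session")
def head():
    return make_template_head()


@pytest.fixture(scope="session")
def montage(head):
    return make_template_montage(head)


@pytest.fixture(scope="session")
def small_sourcespace(head):
    return make_source_space(head, 500)


@pytest.fixture(scope="session")
def small_leadfield(head, montage, small_sourcespace):
    return compute_leadfield(head, montage, small_sourcespace)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
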