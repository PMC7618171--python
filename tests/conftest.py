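import numpy as np
import pytest

from painrct.nnrf import Template, build_template


@pytest.fixture(scope="session")
def template() -> Template:
    return build_template()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
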