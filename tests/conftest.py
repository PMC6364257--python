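import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from exudate import PhantomSpec, generate_phantom, prepare_image


@pytest.fixture(scope="session")
def phantom_default():
    """One default 512x512 phantom with its ground truth."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def prepared_default(phantom_default):
    """Stage products of the default phantom, computed once per session."""
    image, _ = phantom_default
    return prepare_image(image)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
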