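import numpy as np
import pytest

from octdme.phantom import PhantomSpec, render_clean_bscan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tall_spec():
    """Phantom tall enough for the full 325/30/340 crop without padding."""
    return PhantomSpec(rows=448, cols=512)


@pytest.fixture(scope="session")
def tall_clean(tall_spec):
    return render_clean_bscan(tall_spec)
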