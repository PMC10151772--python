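import pytest

from clonelc import make_germline_repertoire


@pytest.fixture(scope="session")
def repertoire():
    """A 30 V / 4 J / 2 C synthetic germline repertoire shared across tests."""
    return make_germline_repertoire(n_v=30, n_j=4, seed=1)
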