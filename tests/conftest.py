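import pytest

from metalloform import MetalloformComposition, mt3


@pytest.fixture(scope="session")
def protein():
    """The vendored human MT3 sequence (68 residues, 20 Cys)."""
    return mt3()


@pytest.fixture(scope="session")
def cu4zn4ox():
    return MetalloformComposition(n_cu=4, n_zn=4, n_ss=2, z=5)


@pytest.fixture(scope="session")
def cu4nem2ox():
    return MetalloformComposition(n_cu=4, n_nem=2, n_ss=2, z=5)
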