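import numpy as np
import pytest

from lipoforge import build_assembly, build_extended_monomer, parse_lipopeptide


@pytest.fixture(scope="session")
def kyk_spec():
    return parse_lipopeptide("C16-KYK")


@pytest.fixture(scope="session")
def kwk_spec():
    return parse_lipopeptide("C16-KWK")


@pytest.fixture(scope="session")
def kyk_monomer(kyk_spec):
    return build_extended_monomer(kyk_spec)


@pytest.fixture(scope="session")
def kyk_bilayer_256():
    """The full nanotape construction used by several analyses."""
    return build_assembly("C16-KYK", "bilayer", 256)


@pytest.fixture(scope="session")
def kyk_bilayer_64():
    """Smaller bilayer for cheaper per-metric tests."""
    return build_assembly("C16-KYK", "bilayer", 64)


@pytest.fixture(scope="session")
def wkk_fibril_64():
    return build_assembly("C16-WKK", "fibril", 64)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(11)
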