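import pytest

from tillseq import build_scheme, synthetic_refs


@pytest.fixture(scope="session")
def full_scheme():
    """The canonical screen layout: 8 plates of 8 rows x 12 columns."""
    return build_scheme(8, 8, 12)


@pytest.fixture(scope="session")
def small_scheme():
    """A 2x2x3 layout (12 individuals, 7 pools) for brute-force checks."""
    return build_scheme(2, 2, 3)


@pytest.fixture(scope="session")
def one_amplicon():
    return synthetic_refs(1, 200, seed=3)


@pytest.fixture(scope="session")
def two_amplicons():
    return synthetic_refs(2, 150, seed=11)
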