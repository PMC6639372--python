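import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from targetnet import assemble, make_golden_fixture


@pytest.fixture(scope="session")
def small_dataset():
    """200-gene frozen-seed synthetic study (14 cell lines, 10 pairs)."""
    return make_golden_fixture("small")


@pytest.fixture(scope="session")
def small_features(small_dataset):
    ds = small_dataset
    return assemble(ds.network, ds.catalog, ds.dependency, variant="primary")


@pytest.fixture(scope="session")
def medium_dataset():
    """2,000-gene frozen-seed study at the generator's default settings."""
    return make_golden_fixture("medium")


@pytest.fixture(scope="session")
def medium_features(medium_dataset):
    ds = medium_dataset
    return assemble(ds.network, ds.catalog, ds.dependency, variant="primary")
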