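import pytest
from hypothesis import settings

from citrusauth import build_default_catalog, catalog_index, synth_anchor_series

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def catalog():
    return build_default_catalog()


@pytest.fixture(scope="session")
def records_by_id(catalog):
    return catalog_index(catalog)


@pytest.fixture(scope="session")
def anchors():
    return synth_anchor_series()
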