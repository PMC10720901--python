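import pytest

from hemoloop import BLOOD, DING, HO, TZ


@pytest.fixture(params=["HO", "TZ", "Ding-PAI"])
def constants(request):
    """Each shipped power-law constant set in turn."""
    return {"HO": HO, "TZ": TZ, "Ding-PAI": DING}[request.param]


@pytest.fixture
def all_constants():
    return [HO, TZ, DING]


@pytest.fixture
def blood():
    return BLOOD
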