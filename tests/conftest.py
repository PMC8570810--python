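import pytest

from targetctl.synthetic import TOY_NAMES, toy_fixture


@pytest.fixture(params=TOY_NAMES)
def toy(request):
    """(name, network, problem) for each named toy instance."""
    net, prob = toy_fixture(request.param)
    return request.param, net, prob
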