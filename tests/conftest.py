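import pytest

from skullnet.synthetic import fixture


@pytest.fixture
def two_triangle():
    return fixture("two_triangle_bridge")


@pytest.fixture
def triangle():
    return fixture("triangle")


@pytest.fixture
def path3():
    return fixture("path3")


@pytest.fixture
def star4():
    return fixture("star4")


@pytest.fixture
def square():
    return fixture("square")
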