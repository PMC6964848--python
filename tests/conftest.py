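import pytest

from fermpipe import fixtures as fx
from fermpipe.envelope import OxygenPolicy, build_module
from fermpipe.serial_pipeline import FermentationSetup, Organism


@pytest.fixture
def toy_a():
    return fx.make_toy_A()


@pytest.fixture
def toy_b():
    return fx.make_toy_B()


@pytest.fixture
def registry_a():
    return fx.toy_registry_A()


@pytest.fixture
def registry_b():
    return fx.toy_registry_B()


@pytest.fixture
def media1():
    return fx.media_m1()


@pytest.fixture
def media2():
    return fx.media_m2()


@pytest.fixture
def module_a(toy_a, media1, registry_a):
    return build_module(toy_a, media1, "etoh", registry_a, OxygenPolicy.anaerobic())


@pytest.fixture
def setup_a(toy_a, media1, registry_a):
    return FermentationSetup(
        organisms=[Organism(toy_a, registry_a)],
        media=media1,
        target="etoh",
        oxygen=[OxygenPolicy.anaerobic()],
        compound_weights=fx.toy_compound_weights(),
    )


@pytest.fixture
def setup_ab(toy_a, toy_b, media2, registry_a, registry_b):
    return FermentationSetup(
        organisms=[Organism(toy_a, registry_a), Organism(toy_b, registry_b)],
        media=media2,
        target="etoh",
        oxygen=[OxygenPolicy.anaerobic()] * 2,
        compound_weights=fx.toy_compound_weights(),
    )
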