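import pytest

from boolsense import fixtures as fx
from boolsense.screen import screen_system


@pytest.fixture(scope="session")
def fig2():
    return fx.fig2_system()


@pytest.fixture(scope="session")
def embryo_base():
    """Mid-to-late embryo system with the roster minus the double morphants."""
    return fx.embryo_system("mid_late", include_double_morphants=False)


@pytest.fixture(scope="session")
def embryo_full():
    return fx.embryo_system("mid_late", include_double_morphants=True)


@pytest.fixture(scope="session")
def embryo_base_screen(embryo_base):
    system, conditions = embryo_base
    return system, screen_system(system, conditions)


@pytest.fixture(scope="session")
def embryo_full_screen(embryo_full):
    system, conditions = embryo_full
    return system, screen_system(system, conditions)
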