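import pytest

from ffrct.config import Fluid, paper_defaults
from ffrct.experiments import setup_study
from ffrct.geometry import EmulatorConfig, build_porcine_lad_emulator


@pytest.fixture(scope="session")
def fluid() -> Fluid:
    return Fluid()


@pytest.fixture(scope="session")
def emulator_tree():
    return build_porcine_lad_emulator(EmulatorConfig())


@pytest.fixture(scope="session")
def study():
    """Calibrated study context with the physiological default preset."""
    return setup_study(paper_defaults())
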