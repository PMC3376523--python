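import pytest

from eduecon.config import (
    build_breakeven_scenario,
    build_cost_structure,
    load_default_config,
)
from eduecon.cost_model import FACE_TO_FACE, WEB


@pytest.fixture(scope="session")
def default_config():
    return load_default_config()


@pytest.fixture(scope="session")
def structures(default_config):
    return {
        mode: build_cost_structure(cfg)
        for mode, cfg in default_config.cost_structures.items()
    }


@pytest.fixture(scope="session")
def web_primary(structures, default_config):
    """Web primary break-even scenario: FC 1590, VC 8, fee 250, cap 20."""
    return build_breakeven_scenario(structures[WEB], default_config.breakeven)


@pytest.fixture(scope="session")
def f2f_primary(structures, default_config):
    """Face-to-face primary scenario: FC 3060, VC 35, fee 250, cap 20."""
    return build_breakeven_scenario(structures[FACE_TO_FACE], default_config.breakeven)
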