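import numpy as np
import pytest

from cagmosaic import AlleleStructure, StutterParams
from cagmosaic.repeat_genotyper import DEFAULT_ANCHOR_3P, DEFAULT_ANCHOR_5P


@pytest.fixture(scope="session")
def anchors() -> tuple[str, str]:
    return DEFAULT_ANCHOR_5P, DEFAULT_ANCHOR_3P


@pytest.fixture(scope="session")
def calibrated_params() -> StutterParams:
    return StutterParams.calibrated_default()


@pytest.fixture(scope="session")
def no_stutter() -> StutterParams:
    return StutterParams(p_minus=0.0, p_plus=0.0, cycles=30, length_scaling=1.0)


def make_read(structure: AlleleStructure, a5: str = DEFAULT_ANCHOR_5P,
              a3: str = DEFAULT_ANCHOR_3P) -> str:
    return a5 + structure.to_sequence() + a3


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240304)
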