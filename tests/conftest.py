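import numpy as np
import pytest

from sulfoscreen import simulate as sim
from sulfoscreen.kinetics import NoiseModel


@pytest.fixture(scope="session")
def glycan_library():
    return sim.builtin_glycan_library()


@pytest.fixture(scope="session")
def enzymes():
    return sim.builtin_enzymes()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def mini_screen():
    """Small deterministic screen with planted hits."""
    cfg = sim.ScreenConfig(n_plates=3, seed=101,
                           noise=NoiseModel(sd_additive=5.0))
    return sim.simulate_screen(cfg)


def make_profile(cls: str, seed: int = 7, rate: float = 0.3) -> sim.WellProfile:
    """Well profile of a given class with fixed planted rates."""
    sulf, generic, hex_s, hex_a, auto = sim.CLASS_RATE_MAP[cls]
    return sim.WellProfile(
        well_id=f"{cls[:8]}", role="clone", true_class=cls,
        sulfatase_rate=rate if sulf else 0.0,
        generic_sulfatase=generic,
        hex_sulfated_rate=rate if hex_s else 0.0,
        hex_asulfated_rate=rate if hex_a else 0.0,
        autofluor_rate=40.0 if auto else 0.0,
    )
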