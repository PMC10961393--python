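import numpy as np
import pytest

from intrav1.cohort import EffectSpec, simulate_cohort
from intrav1.design import make_block_schedule
from intrav1.retinotopy import build_retinotopic_map


@pytest.fixture(scope="session")
def small_map():
    return build_retinotopic_map(16, max_ecc=4.0, seed=7)


@pytest.fixture(scope="session")
def schedule4():
    return make_block_schedule(4, seed=11)


@pytest.fixture(scope="session")
def schedule5():
    return make_block_schedule(5, seed=11)


@pytest.fixture(scope="session")
def null_cohort(small_map, schedule4):
    return simulate_cohort(6, small_map, schedule4, EffectSpec.null(), seed=3)


@pytest.fixture(scope="session")
def effect_cohort(schedule4):
    rmap = build_retinotopic_map(40, seed=5)
    return simulate_cohort(
        10, rmap, schedule4, EffectSpec.level_network(), seed=5
    ), rmap
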