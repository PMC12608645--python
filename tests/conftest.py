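import numpy as np
import pytest

from metaspheroid.environment import o2_mmHg_to_mM, proton_from_ph
from metaspheroid.metabolism import get_params
from metaspheroid.state import LocalEnvironment


@pytest.fixture(scope="session")
def params():
    return get_params()


@pytest.fixture
def rich_env():
    """Well-fed normoxic medium: 38 mmHg oxygen, 6 mM glucose, pH 7.4."""
    return LocalEnvironment(
        oxygen=o2_mmHg_to_mM(38.0),
        glucose_e=6.0,
        lactate_e=0.1,
        proton_e=proton_from_ph(7.4),
    )


@pytest.fixture
def hypoxic_env():
    return LocalEnvironment(
        oxygen=o2_mmHg_to_mM(2.0),
        glucose_e=6.0,
        lactate_e=3.0,
        proton_e=proton_from_ph(7.4),
    )


def relax(state, env, hours, **kw):
    from metaspheroid.metabolism import relax_cell

    return relax_cell(state, env, hours, **kw)


@pytest.fixture(scope="session")
def steady_states():
    """Single-cell steady states in fixed environments, shared by tests."""
    from metaspheroid.metabolism import init_state, relax_cell

    cache = {}

    def get(o2_mmHg, glucose, lactate, ph=7.4, hours=30.0):
        key = (o2_mmHg, glucose, lactate, ph, hours)
        if key not in cache:
            env = LocalEnvironment(o2_mmHg_to_mM(o2_mmHg), glucose, lactate,
                                   proton_from_ph(ph))
            cache[key] = relax_cell(init_state(1.0), env, hours, sigma=0.0)
        return cache[key]

    return get
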