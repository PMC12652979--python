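import numpy as np
import pytest

from erswitch.model import (
    ModelState,
    ParameterSet,
    StressorInput,
    canonical_parameters,
    physiological_state,
)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return canonical_parameters("calibrated_default")


@pytest.fixture(scope="session")
def phys_init(params) -> ModelState:
    return physiological_state(params)


@pytest.fixture(scope="session")
def zero_rate_params(params) -> ParameterSet:
    """All rate constants zero; Michaelis constants and totals untouched."""
    from erswitch.model import RATE_FIELDS

    return params.with_rates(**{name: 0.0 for name in RATE_FIELDS})


def random_admissible_states(params, n, seed):
    """Seeded admissible states: inside the box, pools respected."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        aut_a = rng.uniform(0, params.aut_t)
        aut_i = rng.uniform(0, params.aut_t - aut_a)
        out.append(
            ModelState(
                upr=rng.uniform(0, params.upr_t),
                bcl2=rng.uniform(0, params.bcl2_t),
                aut_a=aut_a,
                aut_i=aut_i,
                apo_a=rng.uniform(0, params.apo_t),
            )
        )
    return out


@pytest.fixture(scope="session")
def stress_inputs():
    """The study's treatment settings as constant inputs."""
    return {
        "none": StressorInput(),
        "tm_low": StressorInput(stress=5.0),
        "tm_high": StressorInput(stress=50.0),
        "tg_low": StressorInput(stress=5.0, tg=0.25),
        "tg_high": StressorInput(stress=50.0, tg=0.25),
        "rescue_high": StressorInput(stress=50.0, kaua_mult=10.0),
    }
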