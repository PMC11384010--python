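import numpy as np
import pytest

from akdyn.params import (
    Conditions,
    ConformationalRates,
    ModelParameters,
    wild_type_parameters,
)


@pytest.fixture(scope="session")
def wt_params():
    return wild_type_parameters(0.0)


@pytest.fixture(scope="session")
def wt_params_urea():
    return wild_type_parameters(0.8)


def random_model(rng: np.random.Generator) -> tuple[ModelParameters, Conditions]:
    """A random, physically plausible parameter set and condition."""
    kc_apo = 10.0 ** rng.uniform(-1.5, 0.5)
    kc_atp = 10.0 ** rng.uniform(-1.0, 1.0)
    rates = ConformationalRates.from_kc(
        kc_apo, kc_atp, relaxation_rate=10.0 ** rng.uniform(3.0, 5.0)
    )
    params = ModelParameters(
        k_cat=10.0 ** rng.uniform(1.5, 4.0),
        k_r_T=10.0 ** rng.uniform(1.5, 4.0),
        k_r_M=10.0 ** rng.uniform(1.0, 3.5),
        Kd_ATP=10.0 ** rng.uniform(-5.0, -3.0),
        Kd_AMP=10.0 ** rng.uniform(-5.0, -3.0),
        conformational_rates=rates,
    )
    cond = Conditions(
        atp=10.0 ** rng.uniform(-5.0, -2.0),
        amp=10.0 ** rng.uniform(-5.0, -2.0),
    )
    return params, cond
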