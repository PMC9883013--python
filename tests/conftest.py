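import numpy as np
import pytest

from sertcycle import (
    LigandConditions,
    RateConstantSet,
    build_sert_cycle,
)


@pytest.fixture(scope="session")
def default_model():
    return build_sert_cycle()


@pytest.fixture(scope="session")
def model_at_10uM(default_model):
    return default_model.with_conditions(S_out=10e-6)


def random_rate_set(rng: np.random.Generator) -> RateConstantSet:
    """Random positive rate constants within physiological magnitudes."""
    return RateConstantSet(
        kon_K=10 ** rng.uniform(5, 7),
        koff_K=10 ** rng.uniform(2, 4),
        kon_Na=10 ** rng.uniform(5, 7),
        koff_Na=10 ** rng.uniform(2, 4),
        kon_S=10 ** rng.uniform(6, 8),
        koff_S=10 ** rng.uniform(1, 3),
        k_ToNaS_TiNaS=10 ** rng.uniform(0, 2.5),
        k_TiNaS_ToNaS=10 ** rng.uniform(0, 2.5),
        k_TiK_ToK=10 ** rng.uniform(-0.5, 1.5),
        k_ToK_TiK=10 ** rng.uniform(-0.5, 1.5),
    )


def random_conditions(rng: np.random.Generator) -> LigandConditions:
    return LigandConditions(
        Na_out=rng.uniform(0.05, 0.2),
        K_out=rng.uniform(0.0, 0.01),
        S_out=10 ** rng.uniform(-8, -4),
        Na_in=rng.uniform(0.0, 0.02),
        K_in=rng.uniform(0.05, 0.2),
        S_in=0.0,
    )
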