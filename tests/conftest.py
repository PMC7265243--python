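import numpy as np
import pytest

from mitophos import GeneratorConfig, canonical_v1, generate_dataset


@pytest.fixture(scope="session")
def params():
    return canonical_v1()


@pytest.fixture(scope="session")
def small_dataset():
    """A small spiked benchmark shared across IO/pipeline tests."""
    cfg = GeneratorConfig(n_sites=400, n_proteins=120, frac_changed=0.1,
                          frac_missing=0.05, seed=11)
    return generate_dataset(cfg)


def random_in_bounds_state(rng: np.random.Generator, p):
    """Draw a random state satisfying every physical bound."""
    from mitophos import ModelState

    BT = rng.uniform(0, 2)
    BP = rng.uniform(0, BT)
    ET = rng.uniform(0, p.ensa_tot)
    Cplx = rng.uniform(0, min(ET, p.b55_tot))
    return ModelState(
        A=rng.uniform(0, 2), BT=BT, BP=BP,
        W=rng.uniform(), C25=rng.uniform(), G=rng.uniform(),
        ET=ET, Cplx=Cplx,
        Se=rng.uniform(), Si=rng.uniform(), Sl=rng.uniform(),
    )
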