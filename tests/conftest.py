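import pytest

from gripmr import (
    LinearEffect,
    NullEffect,
    default_config,
    default_instrument,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def linear_cohort_male():
    """Male-only cohort with a linear true effect of 0.01 kg per nmol/L."""
    cfg = default_config(n=30_000, seed=12, sex_fraction_male=1.0,
                         causal_fn=LinearEffect(0.01))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Mixed-sex cohort with no causal effect but real confounding."""
    cfg = default_config(n=30_000, seed=11, causal_fn=NullEffect())
    return simulate_cohort(cfg)
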