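import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """A paper-anchored 15-animal cohort with measurement noise."""
    from ethopharm import synthetic as syn

    return syn.generate_study(syn.default_config(seed=11))


@pytest.fixture(scope="session")
def default_measures(default_cohort):
    from ethopharm.measures import build_measure_table

    return build_measure_table(default_cohort)


@pytest.fixture(scope="session")
def noiseless_validation():
    """Noiseless validation-regime cohort plus its planted traits."""
    from ethopharm import synthetic as syn
    from ethopharm.measures import build_measure_table

    cfg = syn.validation_config(n_animals=15, seed=5, noiseless=True)
    traits = syn.sample_latent_traits(cfg)
    table = build_measure_table(syn.generate_study(cfg))
    return cfg, traits, table


def planted_trait_expectations(traits: pd.DataFrame, hab_flag: bool) -> pd.DataFrame:
    """Measure-space expectations for planted traits (flag-aware for the
    square-root habituation transform)."""
    from ethopharm.synthetic import TRAIT_MEASURE

    expected = pd.DataFrame(index=traits.index)
    for trait, measure in TRAIT_MEASURE.items():
        col = traits[trait]
        if trait == "loco_habituation":
            col = col.abs() if hab_flag else col ** 2
        expected[measure] = col
    return expected
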