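import pytest

import cortexdyn as cd


@pytest.fixture(scope="session")
def schedule12():
    return cd.demo_schedule(n_scans=12)


@pytest.fixture(scope="session")
def mixed_cohort(schedule12):
    """3-location cohort: shared-recency II/III vs location-specific V."""
    return cd.generate_cohort(
        3,
        400,
        schedule12,
        {
            "II/III": cd.DynamicsSpec("shared_recency"),
            "V": cd.DynamicsSpec("location_specific_lag"),
        },
        seed=1,
    )


@pytest.fixture(scope="session")
def noise_cohort(schedule12):
    """Independent-regime cohort: no history signal, no environment effect."""
    panels, truth = cd.generate_cohort(
        2,
        300,
        schedule12,
        {"II/III": cd.DynamicsSpec("independent", env_effect_scale=0.0)},
        seed=2,
    )
    return panels, truth
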