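import pytest

from prldscreen import (
    PhenotypeModel,
    calibrate_theta,
    nnb_scheme,
    published_scale,
)


@pytest.fixture(scope="session")
def scheme():
    return nnb_scheme()


@pytest.fixture(scope="session")
def a2_degradation():
    """Published degradation scale of the hnRNPA2 context (printed ln(OR))."""
    return published_scale("a2_degradation")


@pytest.fixture(scope="session")
def a2_prion():
    return published_scale("a2_prion")


@pytest.fixture(scope="session")
def screen_model(scheme, a2_degradation, a2_prion):
    """Study-condition generative model: true weights = the A2 degradation
    scale, theta calibrated so ~35% of isolates are latently positive."""
    theta = calibrate_theta(a2_degradation, scheme, seed=0)
    return PhenotypeModel(
        true_scale=a2_degradation,
        theta=theta,
        prion_scale=a2_prion,
    )
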