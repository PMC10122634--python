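import numpy as np
import pytest

from mtufit import SubjectRecord, build_subject_model


@pytest.fixture
def subject():
    """A typically sized child subject."""
    return SubjectRecord(
        id="T01", group="TD", mass=39.2, height_cm=143.7,
        tibia_m=0.33, foot_m=0.206, leg_m=0.693,
    )


@pytest.fixture
def default_model(subject):
    return build_subject_model(subject)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def draw_admissible_fibre(rng):
    """Random fibre curve parameters within bounds, strain gap kept open."""
    eps_zero = rng.uniform(-0.5, 0.45)
    eps_one = rng.uniform(max(0.5, eps_zero + 0.05), 1.5)
    return dict(
        eps_zero_f=eps_zero,
        eps_one_f=eps_one,
        k_low_scale=rng.uniform(0.01, 0.99),
        curviness_f=rng.uniform(0.0, 1.0),
    )


def draw_admissible_tendon(rng):
    return dict(
        eps_one_t=rng.uniform(0.01, 5.0),
        f_toe_t=rng.uniform(0.01, 0.99),
        curviness_t=rng.uniform(0.0, 1.0),
    )
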