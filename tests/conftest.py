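import numpy as np
import pytest

from igsim import PopulationParameters, Subject, compute_lbm


@pytest.fixture
def pop_params():
    return PopulationParameters()


def make_subject(weight=70.0, height=1.75, sex="male", age=40.0,
                 subject_id="s0"):
    bmi = weight / height**2
    from igsim import assign_age_group, assign_bmi_group
    return Subject(
        subject_id=subject_id, age=age, sex=sex, height=height, weight=weight,
        bmi=bmi, lbm=compute_lbm(weight, bmi, sex),
        bmi_group=assign_bmi_group(bmi), age_group=assign_age_group(age),
    )


@pytest.fixture
def adult_subject():
    return make_subject()


def random_individual(rng):
    """A random but physiologic individual-parameter set for solver checks."""
    from igsim import IndividualParameters
    return IndividualParameters(
        cl=rng.uniform(0.03, 0.4),
        vc=rng.uniform(1.0, 6.0),
        q=rng.uniform(0.05, 1.0),
        vp=rng.uniform(1.0, 8.0),
        ka=rng.uniform(0.08, 0.6),
        f=rng.uniform(0.5, 1.0),
        ksyn=rng.uniform(0.0, 0.6),
    )
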