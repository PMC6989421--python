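import numpy as np
import pytest

import craniowarp as cw


@pytest.fixture(scope="session")
def default_head():
    """One canonical synthetic head (skin, bone, landmarks)."""
    return cw.generate_head(cw.HeadParams())


@pytest.fixture(scope="session")
def noiseless_cohort5():
    """Five identical patients, noise-free surgery, aligned."""
    cohort = cw.generate_cohort(
        5,
        variation=cw.CohortVariation.none(),
        surgery=cw.SurgeryParams(noise_sigma_mm=0.0),
        seed=11,
    )
    return [cw.align_dataset(ds) for ds in cohort]


@pytest.fixture(scope="session")
def varied_cohort10():
    """Ten varied patients with 1 mm placement noise, aligned."""
    cohort = cw.generate_cohort(
        10,
        variation=cw.CohortVariation(),
        surgery=cw.SurgeryParams(noise_sigma_mm=1.0),
        seed=7,
    )
    return [cw.align_dataset(ds) for ds in cohort]


def random_rigid(seed, max_angle_deg=180.0, max_shift_mm=50.0):
    return cw.synthetic.random_rigid_transform(seed, max_angle_deg, max_shift_mm)
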