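import numpy as np
import pytest

from tractfa import phantom, study
from tractfa.grids import default_affine


@pytest.fixture(scope="session")
def spec():
    """Default-geometry phantom with desk-scale groups (n=25/group)."""
    return phantom.default_spec(seed=0, groups=study.desk_groups(25),
                                followup_groups={})


@pytest.fixture(scope="session")
def cohort(spec):
    return phantom.assign_scores(spec, phantom.make_cohort(spec))


@pytest.fixture(scope="session")
def control_row(cohort):
    return cohort[cohort.group == "control"].iloc[0]


@pytest.fixture(scope="session")
def nfppa_row(cohort):
    return cohort[cohort.group == "nfppa"].iloc[0]


@pytest.fixture(scope="session")
def control_field(spec, control_row):
    return phantom.build_tensor_field(spec, control_row)


@pytest.fixture(scope="session")
def toi_masks(spec):
    """Tract masks from deterministic tracking on the control template."""
    return study.phantom_toi_masks(spec, seed=0)


@pytest.fixture
def affine2mm():
    return default_affine((2.0, 2.0, 2.0), shape=(20, 20, 20))


def fa_oracle(lam):
    """Independent closed-form FA for one eigenvalue triple (scalar loop)."""
    lam = [max(x, 0.0) for x in lam]
    mean = sum(lam) / 3.0
    num = sum((x - mean) ** 2 for x in lam) ** 0.5
    den = sum(x ** 2 for x in lam) ** 0.5
    if den == 0:
        return 0.0
    return (1.5 ** 0.5) * num / den
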