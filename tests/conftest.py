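import numpy as np
import pytest

import dscbezier as dz


@pytest.fixture(scope="session")
def acq():
    """Default acquisition: 46 frames at 1.65 s, TE 54 ms, 11 baseline."""
    return dz.AcquisitionConfig()


@pytest.fixture(scope="session")
def aif(acq):
    """Default gamma-variate AIF on the acquisition grid."""
    return dz.gamma_variate_aif(18.0, 3.0, 1.5, 11.0, acq.times)


@pytest.fixture(scope="session")
def truth_entry():
    return dz.TissueClassSpec(family="bezier", mtt=3.8, cbf=0.065, delta=0.5)


@pytest.fixture(scope="session")
def truth_residue(truth_entry):
    return dz.make_residue(truth_entry)


@pytest.fixture(scope="session")
def cohort_table():
    return dz.CohortTable.from_fixture()


def random_residue(rng, t_end_range=(2.0, 20.0)):
    """A random valid Bezier residue drawn through the unit-box map."""
    a, b, c, d = rng.uniform(0.05, 0.95, size=4)
    t_end = rng.uniform(*t_end_range)
    return dz.BezierResidue.from_unit_box(a, b, c, d, t_end)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
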