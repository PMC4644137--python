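import numpy as np
import pytest
from hypothesis import settings
from scipy.integrate import solve_ivp

import gadosim as g

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


def ode_profile(subject: g.SubjectPK, dose: float, times: np.ndarray) -> np.ndarray:
    """Independent numerical oracle: integrate the two-compartment ODEs.

    dA1/dt = -(cl/v1) A1 - (q/v1) A1 + (q/v2) A2
    dA2/dt =  (q/v1) A1 - (q/v2) A2

    Returns plasma concentration A1/v1 on `times`.
    """
    v1, v2, q, cl = subject.v1, subject.v2, subject.q_inter, subject.cl_renal

    def rhs(_t, y):
        a1, a2 = y
        return [-(cl / v1) * a1 - (q / v1) * a1 + (q / v2) * a2,
                (q / v1) * a1 - (q / v2) * a2]

    sol = solve_ivp(rhs, (times[0], times[-1]), [dose, 0.0], t_eval=times,
                    method="LSODA", rtol=1e-10, atol=1e-10)
    assert sol.success
    return sol.y[0] / v1


def random_subject(rng: np.random.Generator) -> g.SubjectPK:
    """A physiologically plausible random subject for oracle checks."""
    v1 = rng.uniform(2.0, 8.0)
    v2 = rng.uniform(3.0, 15.0)
    q = rng.uniform(1.0, 6.0)
    cl = rng.uniform(0.1, 1.0)
    return g.SubjectPK.from_micro(v1=v1, v2=v2, q_inter=q, cl_renal=cl)


@pytest.fixture(scope="session")
def compound():
    return g.CompoundParams()


@pytest.fixture(scope="session")
def ref_subject(compound):
    return g.reference_subject(compound)


@pytest.fixture(scope="session")
def default_config():
    return g.StudyConfig()


@pytest.fixture(scope="session")
def default_study(default_config):
    """The canonical study: all eight cohorts under the default design."""
    return {
        label: g.run_study(default_config.design, default_config.cohorts[label],
                           default_config.compound)
        for label in default_config.cohort_order
    }
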