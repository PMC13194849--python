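import numpy as np
import pytest

from dyntac.curves import FrameSchedule, TacCurve
from dyntac.kinetics import FitOptions
from dyntac.pipeline import fit_cohort
from dyntac.synthetic_cohort import AifParams, CohortSpec, gen_cohort, gen_input_function

FAST_FIT = FitOptions(n_grid_starts=4, n_jitter_starts=2)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default_28()


@pytest.fixture(scope="session")
def dense_grid():
    return np.linspace(0.0, 65.0, 6501)


@pytest.fixture(scope="session")
def aif(dense_grid):
    return gen_input_function(AifParams(), dense_grid)


@pytest.fixture(scope="session")
def small_cohort():
    """Low-noise 12-patient cohort shared across tests."""
    spec = CohortSpec(n_patients=12, noise_level=0.02, seed=42)
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    return fit_cohort(small_cohort, FAST_FIT)


def make_survival(n, rng, beta=0.0, marker=None, base_hazard=0.002,
                  admin=900.0, cens_max=1800.0):
    """Exponential survival with optional log-linear marker effect."""
    if marker is None:
        marker = rng.standard_normal(n)
    h = base_hazard * np.exp(beta * marker)
    t_event = rng.exponential(1.0 / h)
    c = np.minimum(admin, rng.uniform(0, cens_max, n))
    return marker, np.minimum(t_event, c), (t_event <= c).astype(int)
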