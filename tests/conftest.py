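import numpy as np
import pytest

import bcscreen as b
from bcscreen.natural_history import natural_course

SEED = 11


@pytest.fixture(scope="session")
def params():
    return b.NaturalHistoryParams()


@pytest.fixture(scope="session")
def cohort(params):
    """A 20k-woman cohort at the calibrated defaults, shared across tests."""
    return b.sample_life_histories(20_000, params, seed=SEED)


@pytest.fixture(scope="session")
def control(cohort):
    return natural_course(cohort)


@pytest.fixture(scope="session")
def comparator_screened(cohort, control):
    return b.apply_screening(cohort, control, b.ScreeningPolicy(), b.MAMMOGRAPHY, seed=SEED)


def assert_courses_equal(a, b_):
    """Exact (NaN-aware) equality of two outcome universes."""
    for f in ("diagnosis_age", "diagnosis_diameter", "bc_death_age", "death_age"):
        np.testing.assert_array_equal(getattr(a, f), getattr(b_, f))
    for f in ("diagnosis_mode", "stage", "death_cause"):
        np.testing.assert_array_equal(getattr(a, f), getattr(b_, f))
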