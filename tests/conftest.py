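import dataclasses

import numpy as np
import pytest

from muscleqmri import CohortConfig, PhantomSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Compact phantom used throughout the unit tests (fast to render/segment)."""
    return PhantomSpec(slice_count=4, in_plane_shape=(64, 64))


@pytest.fixture(scope="session")
def cohort10():
    return simulate_cohort(10, CohortConfig(), seed=1)


@pytest.fixture()
def subject_with_infiltration(cohort10):
    """Factory: clone a subject with a prescribed infiltration trajectory."""

    def make(f):
        f = np.atleast_1d(np.asarray(f, dtype=float))
        weeks = tuple(int(w) for w in CohortConfig().visit_weeks[: len(f)])
        return dataclasses.replace(cohort10[0], infiltration=f, visit_weeks=weeks)

    return make


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0
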