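import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gutpatterns import CohortTable

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Five subjects, one taxon, four days — rosters enumerable by hand.

    Detection histories:
        s1: 1 1 1 0    s2: 1 1 1 0    s3: 1 1 1 1
        s4: 0 0 0 0    s5: 1 0 1 0
    """
    det = np.array(
        [[[1, 1, 1, 0]], [[1, 1, 1, 0]], [[1, 1, 1, 1]], [[0, 0, 0, 0]], [[1, 0, 1, 0]]],
        dtype=float,
    )
    return CohortTable(
        subject_ids=np.array(["s1", "s2", "s3", "s4", "s5"], dtype=object),
        stratum=np.array(["M"] * 5, dtype=object),
        outcome=np.array([0.1, -0.2, 0.3, -1.0, 0.5]),
        detections=det,
        taxon_names=("probe1",),
        timepoint_days=(4, 10, 30, 120),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230942)
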