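import numpy as np
import pytest

from cmrnorms import (
    Subject,
    generate_study_cohorts,
    prisma_trio_defaults,
)
from cmrnorms.monte_carlo import CohortMap, cohort_key


@pytest.fixture(scope="session")
def default_specs():
    return prisma_trio_defaults()


@pytest.fixture(scope="session")
def study_cohorts(default_specs) -> CohortMap:
    """One full synthetic study (all six cohorts), QC applied."""
    return generate_study_cohorts(default_specs, seed=20230)


def cohorts_from_values(**groups) -> CohortMap:
    """Build a CohortMap straight from global-value arrays.

    Keys are ``scanner_map_sex`` strings, e.g. ``prisma_T1_male=[...]``.
    Subjects carry only the global value (no segments), which is all the
    Monte Carlo engine needs.
    """
    cohorts: CohortMap = {}
    for name, values in groups.items():
        scanner, map_type, sex = name.split("_")
        key = cohort_key(scanner, map_type, sex)
        cohorts[key] = [
            Subject(
                id=f"{name}{i}", scanner_label=scanner, sex=sex,
                age=40.0, height=170.0, weight=70.0, heart_rate=60.0,
                global_value=float(v),
            )
            for i, v in enumerate(np.asarray(values, dtype=float))
        ]
    return cohorts
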