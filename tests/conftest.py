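"""Shared fixtures: synthetic cohorts and the hand-checkable micro case."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tvindex.patterns import cluster_profiles, featurize_profiles, label_clusters
from tvindex.synth import CohortSpec, generate_cohort, generate_worked_micro_case
from tvindex.tvi_core import build_profiles

# Expected TVI values of the micro case's three windows (sizes 5/5/2),
# computed by direct arithmetic on the value tuples: for each variable,
# window mean minus pooled mean over all 12 values, divided by the pooled
# sample SD (ddof=1), summed over MAP/BIS/MAC.
MICRO_EXPECTED_TVIS = (
    -0.09076809669755984,
    0.2966207410922914,
    -0.5146316109868233,
)


@pytest.fixture(scope="session")
def micro_case() -> pd.DataFrame:
    return generate_worked_micro_case()


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-case default-spec cohort for fast structural checks."""
    return generate_cohort(CohortSpec(n_cases=120, seed=11))


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return build_profiles(small_cohort.measurements)


@pytest.fixture(scope="session")
def default_cohort_2000():
    """The default study cohort: 2000 cases, default spec, fixed seed."""
    return generate_cohort(CohortSpec(n_cases=2000, seed=17))


@pytest.fixture(scope="session")
def profiles_2000(default_cohort_2000):
    return build_profiles(default_cohort_2000.measurements)


@pytest.fixture(scope="session")
def clustered_2000(default_cohort_2000, profiles_2000):
    X, case_ids = featurize_profiles(profiles_2000.profiles)
    model = cluster_profiles(X, case_ids, k=3, seed=17)
    return label_clusters(model, profiles_2000.profiles), case_ids


def toy_measurements(rows) -> pd.DataFrame:
    """Build a tidy measurements frame from (case, t, variable, value, source) tuples."""
    return pd.DataFrame(
        rows, columns=["case_id", "t_min", "variable", "value", "source"]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
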