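import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from alspheno import (CohortSpec, FeatureTable, assemble_feature_table,
                      generate_cohort, impute_missing_with_mean)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_table(X, y, names=None) -> FeatureTable:
    """Build a FeatureTable from plain arrays (test helper)."""
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [
        f"f{j}" for j in range(X.shape[1])]
    ids = [f"s{i:03d}" for i in range(X.shape[0])]
    data = pd.DataFrame(X, index=ids, columns=names)
    data.index.name = "subject_id"
    return FeatureTable(data, pd.Series(np.asarray(y, dtype=int), index=ids,
                                        name="label"))


@pytest.fixture(scope="session")
def default_bundle():
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def default_table(default_bundle):
    return impute_missing_with_mean(assemble_feature_table(default_bundle))
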