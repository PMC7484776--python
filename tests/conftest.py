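from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fluidsense.datatypes import FEATURE_NAMES, CohortDataset


def two_cloud_cohort(
    n_majority: int,
    n_minority: int,
    distance: float,
    seed: int = 0,
    minority_group: str = "baseline",
    majority_group: str = "control",
) -> CohortDataset:
    """Two Gaussian clouds separated along every feature axis.

    The minority group is shifted by ``distance`` SDs on all 15 features;
    one subject per recording.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_majority + n_minority):
        group = minority_group if i < n_minority else majority_group
        mean = distance if group == minority_group else 0.0
        feats = rng.normal(mean, 1.0, len(FEATURE_NAMES))
        rows.append(
            {"subject_id": f"S{i:03d}", "group": group, **dict(zip(FEATURE_NAMES, feats))}
        )
    return CohortDataset(table=pd.DataFrame(rows))


@pytest.fixture
def separable_cohort() -> CohortDataset:
    return two_cloud_cohort(30, 30, 10.0, seed=11)
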