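import numpy as np
import pandas as pd
import pytest

import ferroscore as fs


@pytest.fixture(scope="session")
def ref_params() -> fs.SimParams:
    """Reference study conditions for the synthetic cohorts."""
    return fs.SimParams(seed=11)


@pytest.fixture(scope="session")
def cohort(ref_params) -> fs.SyntheticCohort:
    return fs.generate_cohort(ref_params)


@pytest.fixture(scope="session")
def activity(cohort) -> pd.DataFrame:
    """Drive/suppress activities and RFL for the reference cohort."""
    scores = fs.score_matrix(
        cohort.expression, [cohort.pair.drivers, cohort.pair.suppressors]
    )
    return fs.compute_rfl(scores.iloc[0], scores.iloc[1])


@pytest.fixture()
def tiny_matrix() -> pd.DataFrame:
    """5 genes x 3 samples with strictly decreasing expression in sample s1."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(1, 6)]
    data = {
        "s1": [5.0, 4.0, 3.0, 2.0, 1.0],
        "s2": rng.normal(size=5),
        "s3": rng.normal(size=5),
    }
    return pd.DataFrame(data, index=genes)
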