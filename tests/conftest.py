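import logging

import numpy as np
import pandas as pd
import pytest

from reosig.io_model import ExpressionMatrix, SurvivalData
from reosig.synthetic_data import SimConfig, simulate_cohort

logging.getLogger("reosig").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort (one fixed seed)."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture()
def toy_expr():
    """Tiny 4-gene x 3-sample matrix with known orderings."""
    df = pd.DataFrame(
        {
            "s1": [5.0, 3.0, 8.0, 1.0],
            "s2": [2.0, 6.0, 7.0, 4.0],
            "s3": [9.0, 1.0, 2.0, 3.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return ExpressionMatrix(df)


@pytest.fixture()
def toy_surv():
    return SurvivalData(["s1", "s2", "s3"], [12.0, 30.0, 55.0], [1, 1, 0])


def builder_candidates(truth, n_noise: int = 18):
    """Candidate gene list for signature building: planted genes + noise genes.

    Mirrors the upstream screen's output size (a few dozen genes), which is
    what the pair builder consumes in practice.
    """
    planted = [g for p in truth.planted_pairs for g in p]
    n_planted = len(planted)
    noise = [f"G{i:04d}" for i in range(n_planted + 1, n_planted + 1 + n_noise)]
    return planted + noise
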