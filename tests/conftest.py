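import numpy as np
import pandas as pd
import pytest

from targetmeta.cohorts import ExpressionCohort
from targetmeta.synthetic import (
    SyntheticStudyConfig,
    generate_ancillary,
    generate_multicohort,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 3 cohorts, 200 genes, planted target effect 1.0."""
    return SyntheticStudyConfig(
        n_cohorts=3, tumor_n=30, control_n=25, n_genes=200,
        n_up_genes=20, coexpr_block_size=15,
        n_gene_sets=8, set_size_range=(10, 30), seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_multicohort(small_config, 7)


@pytest.fixture(scope="session")
def small_ancillary(small_config, small_study):
    cohorts, truth = small_study
    return generate_ancillary(small_config, truth, 7, cohorts)


def make_cohort(values, groups=None, study_id="S1", platform_id="P1", batch=None,
                clinical=None):
    """Hand-build a cohort from {gene: [values...]} and a "t"/"c" group string.

    ``groups=None`` labels the first half tumor and the rest control.
    """
    frame = pd.DataFrame(values).T
    frame.columns = [f"smp{i + 1}" for i in range(frame.shape[1])]
    n = frame.shape[1]
    if groups is None:
        labels = ["tumor"] * (n // 2) + ["control"] * (n - n // 2)
    else:
        labels = [{"t": "tumor", "c": "control"}[ch] for ch in groups]
    groups = pd.Series(labels, index=frame.columns)
    if batch is not None:
        batch = pd.Series(list(batch), index=frame.columns)
    return ExpressionCohort(study_id=study_id, platform_id=platform_id,
                            values=frame, groups=groups, batch=batch,
                            clinical=clinical)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
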