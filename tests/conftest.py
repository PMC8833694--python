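import numpy as np
import pytest

from lnscore import CohortSpec, PipelineConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-scale cohort: 5 tumor + 3 control subjects."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def default_pipeline_result(default_cohort):
    """Full pipeline run on the default cohort (shared; read-only)."""
    return run_pipeline(PipelineConfig(), default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
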