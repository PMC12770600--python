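import warnings

import pytest

from neurotimescales import CohortSpec, NoCrossingWarning, generate_cohort
from neurotimescales.pipeline import cohort_metric_table


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (90 scans), shared across tests."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def default_metric_table(default_cohort):
    """Per-ROI metric table of the default cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoCrossingWarning)
        return cohort_metric_table(default_cohort)
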