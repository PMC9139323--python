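import warnings

import pytest

from assayval.core import StudyDesign


@pytest.fixture(autouse=True)
def _silence_truncation_warnings():
    # generators warn when Gaussian noise drives a concentration below 0;
    # irrelevant for the statistical assertions here
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*truncated.*")
        yield


@pytest.fixture
def single_site_design() -> StudyDesign:
    """20 days x 2 runs/day x 3 replicates (480 results over 4 pools)."""
    return StudyDesign("precision_single", {"day": 20, "run": 2, "replicate": 3})


@pytest.fixture
def multi_site_design() -> StudyDesign:
    """3 sites x 5 days x 6 replicates, one run per day."""
    return StudyDesign("precision_multi", {"site": 3, "day": 5, "replicate": 6})
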