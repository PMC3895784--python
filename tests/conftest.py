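import math

import pytest

from txbenefit import RelativeRiskProfile

# the Rao-cohort wait-list anchor: 51% four-year survival
M_ANCHOR = -math.log(0.51) / 4.0


@pytest.fixture
def paper_profile() -> RelativeRiskProfile:
    """Reduced risk begins at the end of the first year."""
    return RelativeRiskProfile.preset("paper")


@pytest.fixture
def tm_profile() -> RelativeRiskProfile:
    """Equal-risk period extended through 1.2 years (table-matching preset)."""
    return RelativeRiskProfile.preset("table_matching")


@pytest.fixture
def identity_profile() -> RelativeRiskProfile:
    return RelativeRiskProfile(((0.5, 1.0), (math.inf, 1.0)))
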