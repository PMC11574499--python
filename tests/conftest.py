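import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from prepclaims import Codebook, PharmacyClaim, SimConfig, generate_cohort

D0 = dt.date(2012, 1, 1)


def day(n: int) -> dt.date:
    """Study day n as a calendar date (day 0 = 2012-01-01)."""
    return D0 + dt.timedelta(days=n)


def tdf_claim(pid: str, start_day: int, supply: int, claim_id: str,
              gpi: str = "1210990230") -> PharmacyClaim:
    return PharmacyClaim(pid, day(start_day), supply, gpi, claim_id)


@pytest.fixture(scope="session")
def book() -> Codebook:
    return Codebook()


@pytest.fixture(scope="session")
def mixed_cohort():
    """A mid-size noise-free cohort covering all five indications."""
    return generate_cohort(SimConfig(n_patients=200, seed=11))
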