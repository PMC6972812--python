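import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from incsurv.records import EncounterRecord

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")

STUDY_END = dt.date(2018, 4, 30)


def make_record(
    individual_id="t-001",
    site="north",
    age_class="adult",
    residency="translocated",
    method="radiotelemetry",
    first_observed=dt.date(2014, 10, 1),
    last_alive=dt.date(2015, 10, 1),
    first_dead=None,
    midline_carapace_length=None,
):
    return EncounterRecord(
        individual_id=individual_id,
        site=site,
        age_class=age_class,
        residency=residency,
        method=method,
        first_observed=first_observed,
        last_alive=last_alive,
        first_dead=first_dead,
        midline_carapace_length=midline_carapace_length,
    )


@pytest.fixture
def study_end():
    return STUDY_END


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
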