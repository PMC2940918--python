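"""Shared fixtures: small synthetic microdata sets and reference structures."""

import numpy as np
import pandas as pd
import pytest

from metsburden.conditional import estimate_conditional_matrix
from metsburden.microdata import default_generator_spec, generate_microdata
from metsburden.packs import demo_pack


@pytest.fixture(scope="session")
def small_records():
    """20k-record default-spec microdata, session-cached."""
    return generate_microdata(default_generator_spec(20_000, seed=123))


@pytest.fixture(scope="session")
def reference(small_records):
    return estimate_conditional_matrix(small_records)


@pytest.fixture(scope="session")
def de_pack():
    return demo_pack("DE")


@pytest.fixture()
def hand_records():
    """Ten hand-written weighted records in a single stratum.

    Weighted tallies (hypertensives only, pattern = obesity, low_hdl,
    high_tg, impaired_glucose): '0000' w=3, '1010' w=3, '1111' w=2,
    total hypertensive weight 8.
    """
    rows = [
        # subject_id, htn, obesity, low_hdl, high_tg, ifg, weight
        (0, 1, 0, 0, 0, 0, 1.0),
        (1, 1, 0, 0, 0, 0, 2.0),
        (2, 1, 1, 0, 1, 0, 1.0),
        (3, 1, 1, 0, 1, 0, 2.0),
        (4, 1, 1, 1, 1, 1, 2.0),
        (5, 0, 1, 0, 0, 0, 1.0),
        (6, 0, 0, 1, 0, 0, 2.0),
        (7, 0, 0, 0, 0, 1, 1.5),
        (8, 0, 1, 1, 1, 1, 0.5),
        (9, 0, 0, 0, 1, 0, 1.0),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "hypertension", "obesity", "low_hdl", "high_tg",
            "impaired_glucose", "weight",
        ],
    )
    df["age_band"] = "50-59"
    df["sex"] = "male"
    df["age"] = 55
    return df
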