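import warnings

import pandas as pd
import pytest

from sizeclines import workflow

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def bundle():
    """Default-truth synthetic study system shared across tests."""
    return workflow.simulate_bundle({"n_records": 6000, "seed": 11})


@pytest.fixture()
def record_row():
    """Factory for a single clean raw record with overridable fields."""

    def make(**kw):
        base = {
            "record_id": "r0", "source": "VertNet",
            "decimal_latitude": 40.0, "decimal_longitude": -100.0,
            "year": 1980, "month": 6, "day": 15,
            "sex": "female", "life_stage": "adult",
            "body_mass": 20.0, "total_length": 160.0, "tail_length": 70.0,
        }
        base.update(kw)
        return base

    return make


@pytest.fixture()
def records_frame(record_row):
    """Factory for a raw record DataFrame from per-row overrides."""

    def make(rows):
        return pd.DataFrame([
            record_row(record_id=f"r{i}", **row) for i, row in enumerate(rows)
        ])

    return make
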