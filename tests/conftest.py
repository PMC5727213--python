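"""Shared fixtures: small hand-built tables and one synthetic screen."""

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import aromabsa as ab

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic screen (seed 0), shared read-only."""
    return ab.end_to_end_fixture(ab.SimConfig(seed=0))


@pytest.fixture()
def peak_frame():
    """Three replicates of one sample plus one replicate of another."""
    rows = [
        # sample, replicate, compound, area, quality
        ("S1", 1, "methyl butanoate", 50.0, 95),
        ("S1", 1, "linalool", 150.0, 91),
        ("S1", 2, "methyl butanoate", 60.0, 90),
        ("S1", 2, "linalool", 140.0, 88),
        ("S1", 3, "methyl butanoate", 55.0, 85),
        ("S1", 3, "hexanal", 10.0, 99),  # 1/3 replicates only
        ("S2", 1, "linalool", 80.0, 82),
        ("S2", 2, "linalool", 90.0, 80),  # quality not > 80
        ("S2", 3, "linalool", 85.0, 95),
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "replicate", "compound", "area", "quality"]
    )


@pytest.fixture()
def group_stats_table():
    """Published per-bulk group statistics for the DFA-selected markers."""
    return ab.studydata.group_stats()


@pytest.fixture()
def published_variants(group_stats_table):
    return dict(zip(group_stats_table.feature, group_stats_table.variant))
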