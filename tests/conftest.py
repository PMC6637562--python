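import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_table(rows):
    """Build a spot table from (spot_id, group, replicate, channel, volume)."""
    df = pd.DataFrame(rows, columns=["spot_id", "group", "replicate",
                                     "channel", "volume"])
    df["present"] = True
    return df


@pytest.fixture
def two_group_tables():
    """Tiny hand-built pair of tables: one shared spot, one unique per group."""
    treated = make_table([
        *[("A", "t", r, "total", 100.0) for r in (1, 2, 3, 4)],
        *[("A", "t", r, "phospho", 50.0) for r in (1, 2, 3, 4)],
        *[("B", "t", r, "total", 200.0) for r in (1, 2, 3, 4)],
        *[("B", "t", r, "phospho", 20.0) for r in (1, 2, 3, 4)],
        *[("C", "t", r, "total", 80.0) for r in (1, 2, 3, 4)],
    ])
    control = make_table([
        *[("A", "c", r, "total", 100.0) for r in (1, 2, 3, 4)],
        *[("A", "c", r, "phospho", 50.0) for r in (1, 2, 3, 4)],
        *[("B", "c", r, "total", 200.0) for r in (1, 2, 3, 4)],
        *[("C", "c", r, "total", 80.0) for r in (1, 2, 3, 4)],
        *[("C", "c", r, "phospho", 40.0) for r in (1, 2, 3, 4)],
    ])
    return treated, control
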