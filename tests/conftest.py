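import pytest
from hypothesis import HealthCheck, settings

from wqbench import (
    FarmPanel,
    FarmPeriodRecord,
    PrincipleExtremes,
    PrincipleScores,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def demo_panel() -> FarmPanel:
    """Three-farm, two-period demonstration panel (published WQ results)."""
    rows = {
        "HU": {"t-1": (46.95, 51.65, 20.30, 36.02), "t": (51.53, 50.95, 30.80, 33.38)},
        "SK": {"t-1": (49.11, 50.19, 43.26, 35.37), "t": (52.45, 51.94, 30.55, 40.19)},
        "AT": {"t-1": (57.92, 53.12, 43.29, 44.01), "t": (55.01, 51.14, 56.70, 40.18)},
    }
    records = [
        FarmPeriodRecord(farm, period, PrincipleScores(*scores))
        for farm, periods in rows.items()
        for period, scores in periods.items()
    ]
    return FarmPanel(records, period_order=("t-1", "t"))


@pytest.fixture
def equation_maxima_t() -> PrincipleExtremes:
    """Per-principle period-t maxima as printed in the worked equations."""
    return PrincipleExtremes(PrincipleScores(55.01, 52.29, 56.70, 40.18), pool="t")


@pytest.fixture
def equation_maxima_tm1() -> PrincipleExtremes:
    return PrincipleExtremes(PrincipleScores(57.92, 53.12, 43.29, 44.01), pool="t-1")
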