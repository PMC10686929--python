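import pandas as pd
import pytest

from ddimpact import (
    Arm,
    Domain,
    IndicatorDefinition,
    Polarity,
    Province,
    ZoneRecord,
    build_default_calendar,
)
from ddimpact import fixtures as packaged


@pytest.fixture(scope="session")
def calendar():
    return build_default_calendar()


@pytest.fixture(scope="session")
def packaged_registry():
    return packaged.load_packaged_registry()


@pytest.fixture(scope="session")
def packaged_roster():
    return packaged.load_packaged_roster()


@pytest.fixture(scope="session")
def reported_impacts():
    return packaged.load_reported_impacts()


@pytest.fixture(scope="session")
def reported_domain_counts():
    return packaged.load_reported_domain_counts()


@pytest.fixture
def tiny_registry():
    return [
        IndicatorDefinition(
            indicator_id="cov",
            label="coverage-style indicator",
            domain=Domain.VACCINATION,
            polarity=Polarity.HIGHER_BETTER,
            provinces=frozenset({Province.KONGO_CENTRAL}),
            value_kind="rate",
        ),
        IndicatorDefinition(
            indicator_id="harm",
            label="harm-style indicator",
            domain=Domain.NUTRITIONAL_HEALTH,
            polarity=Polarity.LOWER_BETTER,
            provinces=frozenset({Province.KONGO_CENTRAL}),
            value_kind="count",
        ),
    ]


@pytest.fixture
def tiny_roster():
    return [
        ZoneRecord("p1", Province.KONGO_CENTRAL, Arm.PRO_DS),
        ZoneRecord("p2", Province.KONGO_CENTRAL, Arm.PRO_DS),
        ZoneRecord("c1", Province.KONGO_CENTRAL, Arm.NON_PRO_DS),
        ZoneRecord("c2", Province.KONGO_CENTRAL, Arm.NON_PRO_DS),
    ]


def make_obs(rows):
    """Build an observation frame from (zone, indicator, year, month, value)
    tuples; value None means missing."""
    df = pd.DataFrame(
        rows, columns=["zone_id", "indicator_id", "year", "month", "value"]
    )
    df["value"] = df["value"].astype(float)
    return df


@pytest.fixture
def constant_panel(calendar):
    """Every zone-month value equal to 5.0 for indicator 'cov'."""
    rows = []
    for zone in ("p1", "p2", "c1", "c2"):
        for y, m in calendar.months_in(
            [p.phase_id for p in calendar.phases]
        ):
            rows.append((zone, "cov", y, m, 5.0))
    return make_obs(rows)
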