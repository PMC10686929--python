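"""Packaged reference data.

* ``indicator_registry.csv`` — the 139 indicator x province definitions
  (74 Kongo Central, 65 Ituri) across the six impact domains, with
  polarity assignments reverse-engineered from which movement direction
  the published per-indicator tables list as a positive impact.  Each
  assignment is a reviewable data row.
* ``reported_impacts.csv`` — the published per-indicator impact rows
  (four phase means, %impact, fold, literal) for both provinces.  The
  ``check`` column records, per row, what the four *printed* (rounded)
  means support recomputing: ``exact`` (printed impact reproduces at
  2-decimal rounding), ``sign`` (only the direction reproduces — the
  published value evidently came from unrounded source data),
  ``unstable`` (comparison-arm change is zero at printed precision),
  ``none`` (recomputation lands exactly on zero so not even the sign is
  checkable), or ``malformed`` (the published row prints only three
  means).
* ``reported_domain_counts.csv`` — the published domain x province
  accounting of indicators with / without a positive effect.
* ``zone_roster_synthetic.csv`` — the ten named program-arm health
  zones plus synthetic comparison-zone identifiers (28 Kongo Central,
  29 Ituri; the real comparison-zone names are not published).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from ..registry import (
    IndicatorDefinition,
    ZoneRecord,
    load_registry,
    load_roster,
)

__all__ = [
    "fixture_path",
    "load_packaged_registry",
    "load_packaged_roster",
    "load_reported_impacts",
    "load_reported_domain_counts",
]


def fixture_path(name: str):
    path = files(__package__) / name
    if not path.is_file():
        raise FileNotFoundError(name)
    return path


def load_packaged_registry() -> list[IndicatorDefinition]:
    return load_registry(str(fixture_path("indicator_registry.csv")))


def load_packaged_roster() -> list[ZoneRecord]:
    return load_roster(str(fixture_path("zone_roster_synthetic.csv")))


def load_reported_impacts() -> pd.DataFrame:
    df = pd.read_csv(str(fixture_path("reported_impacts.csv")))
    df["printed_literal"] = df["printed_literal"].astype(str)
    return df


def load_reported_domain_counts() -> pd.DataFrame:
    return pd.read_csv(str(fixture_path("reported_domain_counts.csv")))
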