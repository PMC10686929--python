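"""Indicator registry and zone roster.

An :class:`IndicatorDefinition` records what a monitoring indicator
measures, which of the six impact domains it belongs to, in which
province(s) it is collected, and its *polarity* — whether the desired
movement is an increase (vaccination coverage, service use) or a decrease
(deaths, attrition, infections).  Polarity drives the positive-effect
classification of each estimate; where the desired direction differs by
province (bed occupancy), a per-province override applies.

A :class:`ZoneRecord` assigns each health zone to one province and one
study arm: the program arm (zones purchased services under the program)
or the comparison arm (all other zones of the two provinces).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path


class Domain(str, Enum):
    """The six impact domains the indicators are grouped into."""

    SUPERVISION_MANAGEMENT = "SUPERVISION_MANAGEMENT"
    SERVICE_USE = "SERVICE_USE"
    NUTRITIONAL_HEALTH = "NUTRITIONAL_HEALTH"
    VACCINATION = "VACCINATION"
    REPRODUCTIVE_MATERNAL = "REPRODUCTIVE_MATERNAL"
    NEWBORN_CHILD = "NEWBORN_CHILD"


class Polarity(str, Enum):
    HIGHER_BETTER = "HIGHER_BETTER"
    LOWER_BETTER = "LOWER_BETTER"


class Province(str, Enum):
    KONGO_CENTRAL = "KONGO_CENTRAL"
    ITURI = "ITURI"


class Arm(str, Enum):
    PRO_DS = "PRO_DS"
    NON_PRO_DS = "NON_PRO_DS"


VALUE_KINDS = ("proportion", "rate", "count", "mean")


@dataclass(frozen=True)
class IndicatorDefinition:
    indicator_id: str
    label: str
    domain: Domain
    polarity: Polarity
    provinces: frozenset[Province]
    value_kind: str = "rate"
    #: province -> polarity, for indicators whose desired direction differs
    polarity_overrides: tuple[tuple[Province, Polarity], ...] = ()

    def __post_init__(self) -> None:
        if not self.indicator_id:
            raise ValueError("indicator_id must be non-empty")
        if not self.provinces:
            raise ValueError(
                f"{self.indicator_id}: provinces must be non-empty"
            )
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"{self.indicator_id}: unknown value_kind {self.value_kind!r}"
            )

    def polarity_for(self, province: Province) -> Polarity:
        for prov, pol in self.polarity_overrides:
            if prov == province:
                return pol
        return self.polarity


@dataclass(frozen=True)
class ZoneRecord:
    zone_id: str
    province: Province
    arm: Arm


@dataclass
class RegistryReport:
    """Validation summary of an indicator registry."""

    n_indicators: int
    province_counts: dict[Province, int]
    domain_counts: dict[tuple[Domain, Province], int]
    warnings: list[str] = field(default_factory=list)


def validate_registry(defs: list[IndicatorDefinition]) -> RegistryReport:
    """Check a registry for duplicates and report its marginal counts.

    Raises ``ValueError`` on an empty registry or duplicate indicator ids.
    """
    if not defs:
        raise ValueError("registry is empty")
    seen: set[str] = set()
    for d in defs:
        if d.indicator_id in seen:
            raise ValueError(f"duplicate indicator_id: {d.indicator_id!r}")
        seen.add(d.indicator_id)

    province_counts = {p: 0 for p in Province}
    domain_counts: dict[tuple[Domain, Province], int] = {
        (dom, p): 0 for dom in Domain for p in Province
    }
    for d in defs:
        for p in d.provinces:
            province_counts[p] += 1
            domain_counts[(d.domain, p)] += 1
    return RegistryReport(
        n_indicators=len(defs),
        province_counts=province_counts,
        domain_counts=domain_counts,
    )


def registry_index(
    defs: list[IndicatorDefinition],
) -> dict[str, IndicatorDefinition]:
    validate_registry(defs)
    return {d.indicator_id: d for d in defs}


def roster_index(roster: list[ZoneRecord]) -> dict[str, ZoneRecord]:
    out: dict[str, ZoneRecord] = {}
    for z in roster:
        if z.zone_id in out:
            raise ValueError(f"duplicate zone_id: {z.zone_id!r}")
        out[z.zone_id] = z
    return out


# ---------------------------------------------------------------------------
# file formats
#
# Registry: CSV with header
#   indicator_id,label,domain,polarity,provinces,value_kind,polarity_overrides
# `provinces` is |-separated; `polarity_overrides` is |-separated
# PROVINCE:POLARITY pairs and is usually empty.
#
# Roster: CSV with header zone_id,province,arm
# ---------------------------------------------------------------------------

REGISTRY_HEADER = [
    "indicator_id",
    "label",
    "domain",
    "polarity",
    "provinces",
    "value_kind",
    "polarity_overrides",
]
ROSTER_HEADER = ["zone_id", "province", "arm"]


def load_registry(path: str | Path) -> list[IndicatorDefinition]:
    path = Path(path)
    defs: list[IndicatorDefinition] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames
        ] != REGISTRY_HEADER:
            raise ValueError(
                f"{path}: registry header must be {','.join(REGISTRY_HEADER)}"
            )
        for row in reader:
            overrides = tuple(
                (Province(p), Polarity(q))
                for p, q in (
                    pair.split(":")
                    for pair in row["polarity_overrides"].split("|")
                    if pair
                )
            )
            defs.append(
                IndicatorDefinition(
                    indicator_id=row["indicator_id"].strip(),
                    label=row["label"].strip(),
                    domain=Domain(row["domain"].strip()),
                    polarity=Polarity(row["polarity"].strip()),
                    provinces=frozenset(
                        Province(p)
                        for p in row["provinces"].split("|")
                        if p
                    ),
                    value_kind=row["value_kind"].strip(),
                    polarity_overrides=overrides,
                )
            )
    validate_registry(defs)
    return defs


def save_registry(defs: list[IndicatorDefinition], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_HEADER)
        for d in defs:
            writer.writerow(
                [
                    d.indicator_id,
                    d.label,
                    d.domain.value,
                    d.polarity.value,
                    "|".join(sorted(p.value for p in d.provinces)),
                    d.value_kind,
                    "|".join(
                        f"{p.value}:{q.value}" for p, q in d.polarity_overrides
                    ),
                ]
            )


def load_roster(path: str | Path) -> list[ZoneRecord]:
    path = Path(path)
    roster: list[ZoneRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames
        ] != ROSTER_HEADER:
            raise ValueError(
                f"{path}: roster header must be {','.join(ROSTER_HEADER)}"
            )
        for row in reader:
            roster.append(
                ZoneRecord(
                    zone_id=row["zone_id"].strip(),
                    province=Province(row["province"].strip()),
                    arm=Arm(row["arm"].strip()),
                )
            )
    roster_index(roster)  # duplicate check
    return roster


def save_roster(roster: list[ZoneRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_HEADER)
        for z in roster:
            writer.writerow([z.zone_id, z.province.value, z.arm.value])
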