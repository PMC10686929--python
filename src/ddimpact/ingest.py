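"""Reading and validating observation panels.

Observations are long-format monthly values: one row per
(zone, indicator, calendar month).  The file dialect is fixed — comma
separated, UTF-8, "." decimal mark, header ``zone_id,indicator_id,year,
month,value`` — and an empty value field marks a missing month.  Rows
that fail referential integrity (unknown zone or indicator), carry a
malformed or out-of-span month, or a negative value are rejected
row-by-row with a reason; an unreadable file is a hard error.

The module also applies the design's missing-data rule: an indicator is
dropped from a province's analysis when more than two calendar years of
its series are entirely missing there.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phases import PhaseCalendar
from .registry import (
    IndicatorDefinition,
    Province,
    ZoneRecord,
    registry_index,
    roster_index,
)

OBS_COLUMNS = ["zone_id", "indicator_id", "year", "month", "value"]


@dataclass(frozen=True)
class Observation:
    """One zone x indicator x month value; ``value`` None when missing."""

    zone_id: str
    indicator_id: str
    month: tuple[int, int]
    value: float | None

    @property
    def is_missing(self) -> bool:
        return self.value is None


@dataclass
class IngestReport:
    n_rows_read: int = 0
    n_rows_rejected: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)
    excluded_indicators: list[tuple[str, str, str]] = field(
        default_factory=list
    )
    warnings: list[str] = field(default_factory=list)

    def reject(self, line_no: int, reason: str) -> None:
        self.n_rows_rejected += 1
        self.rejected.append((line_no, reason))

    def to_text(self) -> str:
        lines = [
            f"rows read: {self.n_rows_read}",
            f"rows rejected: {self.n_rows_rejected}",
        ]
        for line_no, reason in self.rejected:
            lines.append(f"  line {line_no}: {reason}")
        for ind, prov, reason in self.excluded_indicators:
            lines.append(f"excluded {ind} ({prov}): {reason}")
        lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines) + "\n"


def read_observations(
    path: str | Path,
    registry: list[IndicatorDefinition],
    roster: list[ZoneRecord],
    calendar: PhaseCalendar | None = None,
) -> tuple[pd.DataFrame, IngestReport]:
    """Read and validate an observations file.

    Returns a DataFrame with columns ``zone_id, indicator_id, year,
    month, value`` (value is float, NaN for missing months) plus an
    :class:`IngestReport` listing every rejected row with its reason.
    """
    path = Path(path)
    ind_idx = registry_index(registry)
    zone_idx = roster_index(roster)
    report = IngestReport()

    try:
        raw = pd.read_csv(
            path,
            dtype={
                "zone_id": str,
                "indicator_id": str,
                "year": str,
                "month": str,
                "value": str,
            },
            keep_default_na=False,
        )
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"cannot read observations file {path}: {exc}")
    if list(raw.columns) != OBS_COLUMNS:
        raise ValueError(
            f"{path}: observations header must be {','.join(OBS_COLUMNS)}"
        )

    rows: list[tuple[str, str, int, int, float]] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        report.n_rows_read += 1
        zone = row.zone_id.strip()
        ind = row.indicator_id.strip()
        if zone not in zone_idx:
            report.reject(line_no, f"unknown zone {zone!r}")
            continue
        if ind not in ind_idx:
            report.reject(line_no, f"unknown indicator {ind!r}")
            continue
        try:
            year, month = int(row.year), int(row.month)
            if not 1 <= month <= 12:
                raise ValueError
        except ValueError:
            report.reject(
                line_no, f"malformed month {row.year!r}-{row.month!r}"
            )
            continue
        if calendar is not None and not calendar.contains((year, month)):
            report.reject(line_no, f"month {year}-{month:02d} outside span")
            continue
        raw_value = row.value.strip()
        if raw_value in ("", "NA", "NaN", "nan", "."):
            value = np.nan
        else:
            try:
                value = float(raw_value)
            except ValueError:
                report.reject(line_no, f"unparseable value {raw_value!r}")
                continue
            if not np.isfinite(value):
                report.reject(line_no, f"non-finite value {raw_value!r}")
                continue
            if value < 0:
                report.reject(line_no, f"negative value {raw_value!r}")
                continue
        rows.append((zone, ind, year, month, value))

    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    df["year"] = df["year"].astype(int) if len(df) else df["year"]
    df["month"] = df["month"].astype(int) if len(df) else df["month"]
    df["value"] = df["value"].astype(float) if len(df) else df["value"]
    return df, report


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation frame in the canonical dialect.

    Missing values become empty fields; numeric values are written with
    ``repr`` precision so that a read/write cycle is lossless.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(",".join(OBS_COLUMNS) + "\n")
    for row in df.itertuples(index=False):
        value = "" if pd.isna(row.value) else repr(float(row.value))
        buf.write(
            f"{row.zone_id},{row.indicator_id},{row.year},{row.month},{value}\n"
        )
    path.write_text(buf.getvalue(), encoding="utf-8")


def to_observation_records(df: pd.DataFrame) -> list[Observation]:
    return [
        Observation(
            zone_id=r.zone_id,
            indicator_id=r.indicator_id,
            month=(int(r.year), int(r.month)),
            value=None if pd.isna(r.value) else float(r.value),
        )
        for r in df.itertuples(index=False)
    ]


def apply_missing_year_exclusion(
    observations: pd.DataFrame,
    registry: list[IndicatorDefinition],
    roster: list[ZoneRecord],
    calendar: PhaseCalendar,
    max_missing_years: int = 2,
    month_rule: bool = False,
    max_missing_months: int = 24,
) -> tuple[set[tuple[str, Province]], list[tuple[str, Province, str]]]:
    """Drop (indicator, province) pairs with too much wholesale missingness.

    A calendar year counts as missing for an (indicator, province) pair
    when no month of that year inside the study span has a present value
    in either arm.  Pairs with more than ``max_missing_years`` such years
    are excluded.  With ``month_rule=True`` the stricter month count is
    used instead: excluded when more than ``max_missing_months`` of the
    pair's span months are missing.

    Returns (retained pairs, excluded list with reasons).  The filter is
    monotone: adding observations can only move pairs from excluded to
    retained, never the reverse.
    """
    zone_prov = {z.zone_id: z.province for z in roster}
    span_months = [
        m
        for m in calendar.months_in(
            [p.phase_id for p in calendar.phases]
        )
    ]
    months_per_year: dict[int, int] = {}
    for y, _m in span_months:
        months_per_year[y] = months_per_year.get(y, 0) + 1
    n_span_months = len(span_months)

    present = observations[observations["value"].notna()].copy()
    if len(present):
        present["province"] = present["zone_id"].map(zone_prov)
    present_keys: dict[tuple[str, Province], set[tuple[int, int]]] = {}
    for r in present.itertuples(index=False):
        present_keys.setdefault((r.indicator_id, r.province), set()).add(
            (int(r.year), int(r.month))
        )

    retained: set[tuple[str, Province]] = set()
    excluded: list[tuple[str, Province, str]] = []
    for d in registry:
        for prov in d.provinces:
            months = present_keys.get((d.indicator_id, prov), set())
            if month_rule:
                n_missing = n_span_months - len(
                    {m for m in months if m in set(span_months)}
                )
                if n_missing > max_missing_months:
                    excluded.append(
                        (
                            d.indicator_id,
                            prov,
                            f"{n_missing} missing months "
                            f"(> {max_missing_months})",
                        )
                    )
                else:
                    retained.add((d.indicator_id, prov))
                continue
            years_present = {y for (y, _m) in months}
            missing_years = [
                y for y in months_per_year if y not in years_present
            ]
            if len(missing_years) > max_missing_years:
                excluded.append(
                    (
                        d.indicator_id,
                        prov,
                        f"{len(missing_years)} fully-missing years "
                        f"(> {max_missing_years}): "
                        + ",".join(str(y) for y in sorted(missing_years)),
                    )
                )
            else:
                retained.add((d.indicator_id, prov))
    return retained, excluded
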