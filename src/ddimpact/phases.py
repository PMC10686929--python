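"""Program phase calendar for the controlled longitudinal design.

The evaluation design partitions the monitoring window into five named
periods: a pre-program year, a baseline year (the program's first year),
and three successive program periods.  The union of the first two defines
the "before" window and the union of the last three the "since" window of
the double-difference comparison.  Months carry no day component because
the routine monitoring data are monthly aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "PHASE_IDS",
    "BEFORE_SET",
    "SINCE_SET",
    "Phase",
    "PhaseCalendar",
    "build_default_calendar",
    "month_index",
    "iter_months",
]

#: The five phase identifiers, in chronological order.
PHASE_IDS: tuple[str, ...] = (
    "T_BEFORE",
    "T_BASELINE",
    "T_PRODS1",
    "T_PRODS2",
    "T_PRODS3",
)

#: Phases pooled into the pre-program ("before") mean.
BEFORE_SET = frozenset({"T_BEFORE", "T_BASELINE"})

#: Phases pooled into the program-period ("since") mean.
SINCE_SET = frozenset({"T_PRODS1", "T_PRODS2", "T_PRODS3"})

Month = tuple[int, int]  # (year, month-of-year)


def month_index(month: Month) -> int:
    """Map a (year, month) pair to a linear month count (Jan year 0 = 0)."""
    year, m = month
    if not 1 <= m <= 12:
        raise ValueError(f"month-of-year out of range: {month!r}")
    return year * 12 + (m - 1)


def iter_months(first: Month, last: Month) -> Iterator[Month]:
    """Yield every calendar month from ``first`` to ``last`` inclusive."""
    i, j = month_index(first), month_index(last)
    if i > j:
        raise ValueError(f"month range reversed: {first!r}..{last!r}")
    for k in range(i, j + 1):
        yield divmod(k, 12)[0], divmod(k, 12)[1] + 1


@dataclass(frozen=True)
class Phase:
    """One named study period spanning whole calendar months, inclusive."""

    phase_id: str
    first_month: Month
    last_month: Month

    def __post_init__(self) -> None:
        if self.phase_id not in PHASE_IDS:
            raise ValueError(f"unknown phase id: {self.phase_id!r}")
        if month_index(self.first_month) > month_index(self.last_month):
            raise ValueError(
                f"phase {self.phase_id}: first month after last month"
            )

    @property
    def n_months(self) -> int:
        return month_index(self.last_month) - month_index(self.first_month) + 1

    def months(self) -> list[Month]:
        return list(iter_months(self.first_month, self.last_month))


@dataclass(frozen=True)
class PhaseCalendar:
    """An ordered, non-overlapping sequence of the five study phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        ids = [p.phase_id for p in self.phases]
        if sorted(ids) != sorted(set(ids)):
            raise ValueError("duplicate phase ids in calendar")
        if set(ids) != set(PHASE_IDS):
            raise ValueError(
                f"calendar must define exactly the phases {PHASE_IDS}"
            )
        if ids != [p for p in PHASE_IDS]:
            raise ValueError("phases out of chronological id order")
        for prev, nxt in zip(self.phases, self.phases[1:]):
            if month_index(nxt.first_month) <= month_index(prev.last_month):
                raise ValueError(
                    f"phases {prev.phase_id} and {nxt.phase_id} overlap "
                    "or are out of order"
                )

    @property
    def first_month(self) -> Month:
        return self.phases[0].first_month

    @property
    def last_month(self) -> Month:
        return self.phases[-1].last_month

    @property
    def n_months(self) -> int:
        """Total number of months from first to last month inclusive."""
        return month_index(self.last_month) - month_index(self.first_month) + 1

    def phase(self, phase_id: str) -> Phase:
        for p in self.phases:
            if p.phase_id == phase_id:
                return p
        raise KeyError(phase_id)

    def phase_of(self, month: Month) -> str | None:
        """Return the phase id containing ``month``, or None if in a gap."""
        k = month_index(month)
        for p in self.phases:
            if month_index(p.first_month) <= k <= month_index(p.last_month):
                return p.phase_id
        return None

    def contains(self, month: Month) -> bool:
        k = month_index(month)
        return month_index(self.first_month) <= k <= month_index(self.last_month)

    def months_in(self, phase_ids) -> list[Month]:
        """All months belonging to any of the given phases, in order."""
        unknown = set(phase_ids) - set(PHASE_IDS)
        if unknown:
            raise ValueError(f"unknown phase ids: {sorted(unknown)}")
        out: list[Month] = []
        for p in self.phases:
            if p.phase_id in phase_ids:
                out.extend(p.months())
        return out

    def years(self) -> list[int]:
        """Calendar years intersecting the study span, ascending."""
        return list(range(self.first_month[0], self.last_month[0] + 1))


def build_default_calendar() -> PhaseCalendar:
    """The default phase calendar of the program evaluation.

    Pre-program year 2016, baseline year 2017 (the program's first year),
    then the three program periods: Jan 2018 - Dec 2020, Jan - Sep 2021,
    and Oct 2021 - Mar 2022.  75 months in total.
    """
    return PhaseCalendar(
        phases=(
            Phase("T_BEFORE", (2016, 1), (2016, 12)),
            Phase("T_BASELINE", (2017, 1), (2017, 12)),
            Phase("T_PRODS1", (2018, 1), (2020, 12)),
            Phase("T_PRODS2", (2021, 1), (2021, 9)),
            Phase("T_PRODS3", (2021, 10), (2022, 3)),
        )
    )
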