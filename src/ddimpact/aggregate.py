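"""Domain x province aggregation of per-indicator estimates.

The published accounting is a dichotomy: each evaluated indicator either
showed the desired movement ("with positive effect") or it did not
("without effect", pooling no-change, wrong-direction and undefined
estimates), so the two counts sum to the domain total.  Percentages are
reported to one decimal and the cross-province "mean" column is the
unweighted average of the two province percentages (60.8 and 70.8
average to 65.8), not the pooled proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .estimator import (
    Classification,
    ImpactEstimate,
    estimates_to_frame,
    round_half_up,
)
from .registry import (
    Domain,
    IndicatorDefinition,
    Province,
    registry_index,
)

__all__ = [
    "DomainSummary",
    "ProvinceSummary",
    "summarize",
    "summaries_from_counts",
    "cross_province_table",
    "render_tables",
]


@dataclass(frozen=True)
class DomainSummary:
    domain: Domain
    province: Province
    n_indicators: int
    n_positive: int
    # finer breakdown of the "without effect" pool
    n_no_change: int = 0
    n_not_positive: int = 0
    n_undefined: int = 0

    def __post_init__(self) -> None:
        if self.n_positive > self.n_indicators:
            raise ValueError("n_positive exceeds n_indicators")

    @property
    def n_no_effect(self) -> int:
        return self.n_indicators - self.n_positive

    @property
    def pct_positive(self) -> float | None:
        if self.n_indicators == 0:
            return None
        return round_half_up(100.0 * self.n_positive / self.n_indicators, 1)

    @property
    def pct_no_effect(self) -> float | None:
        if self.n_indicators == 0:
            return None
        return round_half_up(100.0 * self.n_no_effect / self.n_indicators, 1)


@dataclass(frozen=True)
class ProvinceSummary:
    province: Province
    domains: tuple[DomainSummary, ...]

    @property
    def n_total(self) -> int:
        return sum(d.n_indicators for d in self.domains)

    @property
    def n_positive(self) -> int:
        return sum(d.n_positive for d in self.domains)

    @property
    def n_no_effect(self) -> int:
        return self.n_total - self.n_positive

    @property
    def pct_positive(self) -> float | None:
        if self.n_total == 0:
            return None
        return round_half_up(100.0 * self.n_positive / self.n_total, 1)

    @property
    def pct_no_effect(self) -> float | None:
        if self.n_total == 0:
            return None
        return round_half_up(100.0 * self.n_no_effect / self.n_total, 1)

    def domain(self, domain: Domain) -> DomainSummary:
        for d in self.domains:
            if d.domain == domain:
                return d
        raise KeyError(domain)


def summarize(
    estimates: list[ImpactEstimate],
    registry: list[IndicatorDefinition],
) -> list[ProvinceSummary]:
    """Aggregate classified estimates into per-province domain summaries.

    Every estimate's indicator must be in the registry (hard error
    otherwise).  Domains with no evaluated indicator in a province are
    reported with zero counts.
    """
    idx = registry_index(registry)
    for e in estimates:
        if e.indicator_id not in idx:
            raise KeyError(
                f"estimate for unknown indicator {e.indicator_id!r}"
            )
    provinces = sorted(
        {e.province for e in estimates}, key=lambda p: p.value
    ) or list(Province)
    summaries = []
    for prov in provinces:
        dom_rows = []
        for dom in Domain:
            sub = [
                e
                for e in estimates
                if e.province == prov and idx[e.indicator_id].domain == dom
            ]
            counts = {c: 0 for c in Classification}
            for e in sub:
                counts[e.classification] += 1
            dom_rows.append(
                DomainSummary(
                    domain=dom,
                    province=prov,
                    n_indicators=len(sub),
                    n_positive=counts[Classification.POSITIVE],
                    n_no_change=counts[Classification.NO_CHANGE],
                    n_not_positive=counts[Classification.NOT_POSITIVE],
                    n_undefined=counts[Classification.UNDEFINED],
                )
            )
        summaries.append(ProvinceSummary(province=prov, domains=tuple(dom_rows)))
    return summaries


def summaries_from_counts(counts: pd.DataFrame) -> list[ProvinceSummary]:
    """Build summaries from a (domain, province, n_indicators, n_positive)
    count table, e.g. the packaged published-counts fixture."""
    required = {"domain", "province", "n_indicators", "n_positive"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    summaries = []
    for prov_value, sub in counts.groupby("province", sort=True):
        prov = Province(prov_value)
        dom_rows = []
        for dom in Domain:
            row = sub[sub["domain"] == dom.value]
            if len(row) > 1:
                raise ValueError(
                    f"duplicate count row for {dom.value}/{prov.value}"
                )
            if len(row) == 0:
                dom_rows.append(DomainSummary(dom, prov, 0, 0))
            else:
                r = row.iloc[0]
                dom_rows.append(
                    DomainSummary(
                        dom,
                        prov,
                        int(r["n_indicators"]),
                        int(r["n_positive"]),
                        n_not_positive=int(r["n_indicators"])
                        - int(r["n_positive"]),
                    )
                )
        summaries.append(ProvinceSummary(province=prov, domains=tuple(dom_rows)))
    return summaries


def cross_province_table(summaries: list[ProvinceSummary]) -> pd.DataFrame:
    """Table-of-proportions across provinces, one row per domain plus a
    total row.

    ``mean_pct_positive`` / ``mean_pct_no_effect`` are unweighted means
    of the province percentages; ``pooled_pct_positive`` is also given
    (the two conventions differ: 60.8 and 70.8 average to 65.8 while the
    pooled proportion is 65.5).
    """
    rows = []
    domains = list(Domain) + [None]  # None = total row
    for dom in domains:
        row: dict = {"domain": dom.value if dom else "TOTAL"}
        pcts_pos, pcts_no = [], []
        n_total = n_positive = 0
        for s in summaries:
            d = (
                s.domain(dom)
                if dom
                else DomainSummary(
                    Domain.SUPERVISION_MANAGEMENT,  # placeholder for totals
                    s.province,
                    s.n_total,
                    s.n_positive,
                )
            )
            key = s.province.value.lower()
            row[f"n_{key}"] = d.n_indicators
            row[f"n_positive_{key}"] = d.n_positive
            row[f"pct_positive_{key}"] = d.pct_positive
            row[f"pct_no_effect_{key}"] = d.pct_no_effect
            if d.pct_positive is not None:
                pcts_pos.append(d.pct_positive)
                pcts_no.append(d.pct_no_effect)
            n_total += d.n_indicators
            n_positive += d.n_positive
        row["n_total"] = n_total
        row["n_positive_total"] = n_positive
        row["mean_pct_positive"] = (
            round_half_up(sum(pcts_pos) / len(pcts_pos), 1)
            if pcts_pos
            else None
        )
        row["mean_pct_no_effect"] = (
            round_half_up(sum(pcts_no) / len(pcts_no), 1) if pcts_no else None
        )
        row["pooled_pct_positive"] = (
            round_half_up(100.0 * n_positive / n_total, 1) if n_total else None
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _markdown_table(df: pd.DataFrame) -> str:
    def cell(v) -> str:
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        if isinstance(v, float):
            return f"{v:g}"
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = [
        "| " + " | ".join(cell(v) for v in row) + " |"
        for row in df.itertuples(index=False)
    ]
    return "\n".join([header, sep, *body]) + "\n"


def render_tables(
    summaries: list[ProvinceSummary],
    estimates: list[ImpactEstimate],
    out_dir: str | Path,
    fmt: str = "csv",
) -> list[Path]:
    """Write per-indicator estimate tables and the domain summary.

    ``fmt`` is "csv" (delimited, round-trippable) or "md" (one
    per-indicator table per province plus the summary, human readable).
    Returns the written paths.
    """
    if fmt not in ("csv", "md"):
        raise ValueError(f"unknown format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    est_df = estimates_to_frame(estimates)
    summary_df = cross_province_table(summaries)
    written: list[Path] = []
    if fmt == "csv":
        p = out_dir / "estimates.csv"
        est_df.to_csv(p, index=False)
        written.append(p)
        p = out_dir / "summary.csv"
        summary_df.to_csv(p, index=False)
        written.append(p)
    else:
        parts = []
        provinces = sorted({e.province for e in estimates}, key=lambda p: p.value)
        for prov in provinces:
            parts.append(f"## Per-indicator impacts — {prov.value}\n")
            sub = est_df[est_df["province"] == prov.value].drop(
                columns=["province"]
            )
            parts.append(_markdown_table(sub))
        parts.append("## Proportion of desired results achieved\n")
        parts.append(_markdown_table(summary_df))
        p = out_dir / "report.md"
        p.write_text("\n".join(parts), encoding="utf-8")
        written.append(p)
    return written
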