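"""The double-difference / ratio %-impact estimator.

For each indicator the design compares the change in the program arm
with the change in the comparison arm across the same calendar window:

    double difference = (Ind_since - Ind_before)_program
                        - (Ind_since - Ind_before)_comparison

    %impact = (Ind_since - Ind_before)_program
              / (Ind_since - Ind_before)_comparison  -  1

where Ind_before is the mean over the pre-program and baseline phases
and Ind_since the mean over the three program phases.  The %impact is a
*ratio* of changes, stored as a fraction (0.56 means the program arm's
change was 1.56 times the comparison arm's change); a presentation
option renders it x100.

The statistic is undefined when the comparison arm did not change: an
exactly-zero denominator yields UNDEFINED, and a denominator smaller in
magnitude than the instability threshold is flagged as unstable while
the value is still returned.

The published convention for reading the statistic is reproduced by
:func:`interpret_impact` (the "fold / literal" columns) and the
positive-effect call by :func:`classify_effect`, which combines the sign
of the %impact with the indicator's polarity (whether an increase or a
decrease is the desired movement).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from math import isfinite
from pathlib import Path

import numpy as np
import pandas as pd

from .phases import BEFORE_SET, SINCE_SET, PhaseCalendar
from .registry import (
    Arm,
    IndicatorDefinition,
    Polarity,
    Province,
    ZoneRecord,
    registry_index,
)

__all__ = [
    "EstimatorConfig",
    "Classification",
    "ImpactEstimate",
    "round_half_up",
    "phase_mean",
    "percent_impact",
    "interpret_impact",
    "classify_effect",
    "evaluate_indicator",
    "evaluate_panel",
    "estimates_to_frame",
    "write_estimates",
    "read_estimates",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, as the published tables do."""
    q = Decimal(1).scaleb(-decimals)
    r = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return r + 0.0  # normalize -0.0


class Classification(str, Enum):
    POSITIVE = "POSITIVE"
    NO_CHANGE = "NO_CHANGE"
    NOT_POSITIVE = "NOT_POSITIVE"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunable choices of the estimator.

    ``before_phases`` / ``since_phases`` define the two pooled windows;
    ``denominator_epsilon`` is the absolute comparison-arm change below
    which the ratio is UNDEFINED; ``instability_threshold`` (half the
    published tables' printed resolution) flags near-zero denominators;
    ``rounding_decimals`` governs the displayed/compared rounding;
    ``no_change_tolerance`` widens the rounded-zero band of the
    NO_CHANGE call; ``pooling`` selects pooled zone-month averaging
    ("pooled", every zone-month equally weighted) or the mean of
    per-zone means ("zone_mean").
    """

    before_phases: frozenset[str] = BEFORE_SET
    since_phases: frozenset[str] = SINCE_SET
    denominator_epsilon: float = 1e-9
    instability_threshold: float = 0.05
    rounding_decimals: int = 2
    no_change_tolerance: float = 0.0
    pooling: str = "pooled"

    def __post_init__(self) -> None:
        if not self.before_phases or not self.since_phases:
            raise ValueError("phase sets must be non-empty")
        if self.before_phases & self.since_phases:
            raise ValueError("before and since phase sets must be disjoint")
        if self.denominator_epsilon <= 0 or self.instability_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.no_change_tolerance < 0:
            raise ValueError("no_change_tolerance must be >= 0")
        if self.pooling not in ("pooled", "zone_mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


@dataclass(frozen=True)
class ImpactEstimate:
    """All quantities the design reports for one indicator x province."""

    indicator_id: str
    province: Province
    ind_before_pro: float | None
    ind_since_pro: float | None
    ind_before_non: float | None
    ind_since_non: float | None
    delta_pro: float | None
    delta_non: float | None
    double_difference: float | None
    percent_impact: float | None
    fold: float | None
    literal: str
    classification: Classification
    unstable_denominator: bool
    note: str = ""


def phase_mean(
    observations: pd.DataFrame,
    indicator_id: str,
    arm: Arm,
    phase_set,
    calendar: PhaseCalendar,
    roster: list[ZoneRecord],
    province: Province | None = None,
    pooling: str = "pooled",
) -> float | None:
    """Mean of present zone-month values in the given arm and phases.

    Pooled averaging weights every present zone-month value equally;
    zone-mean averaging first averages within each zone, then across
    zones.  Returns None when no present value exists.
    """
    if not phase_set:
        raise ValueError("phase_set must be non-empty")
    zones = {
        z.zone_id
        for z in roster
        if z.arm == arm and (province is None or z.province == province)
    }
    months = set(calendar.months_in(phase_set))
    sub = observations[
        (observations["indicator_id"] == indicator_id)
        & observations["zone_id"].isin(zones)
        & observations["value"].notna()
    ]
    if len(sub):
        in_months = [
            (int(y), int(m)) in months
            for y, m in zip(sub["year"], sub["month"])
        ]
        sub = sub[np.asarray(in_months, dtype=bool)]
    if not len(sub):
        return None
    if pooling == "pooled":
        return float(sub["value"].mean())
    if pooling == "zone_mean":
        return float(sub.groupby("zone_id")["value"].mean().mean())
    raise ValueError(f"unknown pooling {pooling!r}")


def percent_impact(
    ind_before_pro: float,
    ind_since_pro: float,
    ind_before_non: float,
    ind_since_non: float,
    config: EstimatorConfig = EstimatorConfig(),
) -> tuple[float, float | None, bool]:
    """Double difference and ratio %impact from the four phase means.

    Returns ``(double_difference, percent_impact, unstable)``.  The
    %impact is the fraction (delta_program / delta_comparison) - 1; it is
    None (UNDEFINED) when the comparison-arm change is zero to within
    ``denominator_epsilon``, and ``unstable`` is True whenever that
    change is smaller in magnitude than ``instability_threshold``.
    """
    means = (ind_before_pro, ind_since_pro, ind_before_non, ind_since_non)
    if not all(isinstance(v, (int, float)) and isfinite(v) for v in means):
        raise ValueError(f"phase means must be finite numbers, got {means!r}")
    delta_pro = ind_since_pro - ind_before_pro
    delta_non = ind_since_non - ind_before_non
    dd = delta_pro - delta_non
    if abs(delta_non) < config.denominator_epsilon:
        return dd, None, True
    unstable = abs(delta_non) < config.instability_threshold
    return dd, delta_pro / delta_non - 1.0, unstable


def _fmt(x: float) -> str:
    """Format a rounded magnitude the way the tables print it (no
    trailing zeros: 0.30 -> "0.3", 1.20 -> "1.2", 3.46 -> "3.46")."""
    s = f"{x:.10f}".rstrip("0").rstrip(".")
    return s if s else "0"


def interpret_impact(
    percent_impact_value: float | None,
    config: EstimatorConfig = EstimatorConfig(),
) -> tuple[float | None, str]:
    """The published fold / literal reading of a %impact value.

    With p the %impact rounded to the display precision:

    * p > 0: the program arm's change exceeded the comparison arm's by a
      factor 1 + p; fold = p, read "p times more".
    * p = 0: "No change" relative to the comparison arm.
    * -1 < p < 0: same-direction but attenuated change; fold = -(1 + p),
      the attenuation ratio, read "|fold| times less".
    * p <= -1: opposite-direction change; fold = p, read "|p| times
      less".

    The map is intentionally discontinuous approaching zero from below
    (p = -0.02 reads "0.98 times less" while p = 0 reads "No change");
    this mirrors the published convention exactly.
    """
    if percent_impact_value is None:
        return None, "undefined (unstable denominator)"
    p = round_half_up(percent_impact_value, config.rounding_decimals)
    if abs(p) <= config.no_change_tolerance:
        return 0.0, "No change"
    if p > 0:
        return p, f"{_fmt(p)} times more"
    if p > -1.0:
        fold = round_half_up(-(1.0 + p), config.rounding_decimals)
        return fold, f"{_fmt(abs(fold))} times less"
    return p, f"{_fmt(abs(p))} times less"


def classify_effect(
    percent_impact_value: float | None,
    polarity: Polarity,
    config: EstimatorConfig = EstimatorConfig(),
) -> Classification:
    """Positive-effect call: sign of the %impact against polarity.

    A positive %impact means the indicator moved up more (or down less)
    in the program arm than in the comparison arm; that is a desired
    result only for HIGHER_BETTER indicators, and symmetrically a
    negative %impact is desired for LOWER_BETTER indicators (deaths,
    attrition, infections...).
    """
    if percent_impact_value is None:
        return Classification.UNDEFINED
    p = round_half_up(percent_impact_value, config.rounding_decimals)
    if abs(p) <= config.no_change_tolerance:
        return Classification.NO_CHANGE
    desired_up = polarity == Polarity.HIGHER_BETTER
    if (p > 0) == desired_up:
        return Classification.POSITIVE
    return Classification.NOT_POSITIVE


def evaluate_indicator(
    observations: pd.DataFrame,
    indicator_id: str,
    province: Province,
    roster: list[ZoneRecord],
    registry: list[IndicatorDefinition],
    calendar: PhaseCalendar,
    config: EstimatorConfig = EstimatorConfig(),
) -> ImpactEstimate:
    """Full estimate for one indicator in one province."""
    definition = registry_index(registry).get(indicator_id)
    if definition is None:
        raise KeyError(f"indicator {indicator_id!r} not in registry")
    if province not in definition.provinces:
        raise ValueError(
            f"indicator {indicator_id!r} not collected in {province.value}"
        )
    prov_roster = [z for z in roster if z.province == province]
    means = {}
    for name, arm, phases in (
        ("ind_before_pro", Arm.PRO_DS, config.before_phases),
        ("ind_since_pro", Arm.PRO_DS, config.since_phases),
        ("ind_before_non", Arm.NON_PRO_DS, config.before_phases),
        ("ind_since_non", Arm.NON_PRO_DS, config.since_phases),
    ):
        means[name] = phase_mean(
            observations,
            indicator_id,
            arm,
            phases,
            calendar,
            prov_roster,
            province=province,
            pooling=config.pooling,
        )
    if any(v is None for v in means.values()):
        empty = [k for k, v in means.items() if v is None]
        return ImpactEstimate(
            indicator_id=indicator_id,
            province=province,
            **means,
            delta_pro=None,
            delta_non=None,
            double_difference=None,
            percent_impact=None,
            fold=None,
            literal="undefined (no data)",
            classification=Classification.UNDEFINED,
            unstable_denominator=False,
            note="no present values for: " + ",".join(empty),
        )
    dd, p, unstable = percent_impact(
        means["ind_before_pro"],
        means["ind_since_pro"],
        means["ind_before_non"],
        means["ind_since_non"],
        config,
    )
    fold, literal = interpret_impact(p, config)
    polarity = definition.polarity_for(province)
    classification = classify_effect(p, polarity, config)
    return ImpactEstimate(
        indicator_id=indicator_id,
        province=province,
        **means,
        delta_pro=means["ind_since_pro"] - means["ind_before_pro"],
        delta_non=means["ind_since_non"] - means["ind_before_non"],
        double_difference=dd,
        percent_impact=p,
        fold=fold,
        literal=literal,
        classification=classification,
        unstable_denominator=unstable,
    )


def evaluate_panel(
    observations: pd.DataFrame,
    registry: list[IndicatorDefinition],
    roster: list[ZoneRecord],
    calendar: PhaseCalendar,
    config: EstimatorConfig = EstimatorConfig(),
    retained: set[tuple[str, Province]] | None = None,
) -> list[ImpactEstimate]:
    """Evaluate every retained (indicator, province) pair in the registry."""
    estimates = []
    for d in registry:
        for prov in sorted(d.provinces, key=lambda p: p.value):
            if retained is not None and (d.indicator_id, prov) not in retained:
                continue
            estimates.append(
                evaluate_indicator(
                    observations,
                    d.indicator_id,
                    prov,
                    roster,
                    registry,
                    calendar,
                    config,
                )
            )
    return estimates


ESTIMATE_COLUMNS = [
    "indicator_id",
    "province",
    "ind_before_pro",
    "ind_since_pro",
    "ind_before_non",
    "ind_since_non",
    "delta_pro",
    "delta_non",
    "double_difference",
    "percent_impact",
    "fold",
    "literal",
    "classification",
    "unstable_denominator",
    "note",
]


def estimates_to_frame(estimates: list[ImpactEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "indicator_id": e.indicator_id,
                "province": e.province.value,
                "ind_before_pro": e.ind_before_pro,
                "ind_since_pro": e.ind_since_pro,
                "ind_before_non": e.ind_before_non,
                "ind_since_non": e.ind_since_non,
                "delta_pro": e.delta_pro,
                "delta_non": e.delta_non,
                "double_difference": e.double_difference,
                "percent_impact": e.percent_impact,
                "fold": e.fold,
                "literal": e.literal,
                "classification": e.classification.value,
                "unstable_denominator": e.unstable_denominator,
                "note": e.note,
            }
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def write_estimates(estimates: list[ImpactEstimate], path: str | Path) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False)


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True, na_values=[""])
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: estimate file missing columns {missing}")
    df["note"] = df["note"].fillna("")
    return df


def with_config(config: EstimatorConfig, **overrides) -> EstimatorConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
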