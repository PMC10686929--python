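"""Synthetic monthly two-arm indicator panels with known injected effects.

The generator emulates the study design: two provinces, a small program
arm and a larger comparison arm of health zones, 75 months of monthly
indicator values.  The comparison arm follows a linear secular trend
mu + tau * t; the program arm tracks it exactly during the "before"
phases and receives an additive shift during the "since" phases sized so
that the *expected* since-minus-before change in the program arm equals
(1 + theta) times the comparison arm's change.  theta is therefore the
ground-truth %impact in the estimator's own units, and with zero noise
and no missingness the pipeline recovers it exactly.

Each (zone, indicator) series draws from its own pseudo-random stream
derived from the master seed, so adding zones or indicators never
perturbs existing series.  Missingness is completely at random.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import write_observations
from .phases import BEFORE_SET, SINCE_SET, PhaseCalendar, build_default_calendar, month_index
from .registry import (
    Arm,
    Domain,
    IndicatorDefinition,
    Polarity,
    Province,
    ZoneRecord,
    save_registry,
    save_roster,
)

__all__ = [
    "IndicatorSim",
    "SyntheticConfig",
    "SimulatedDataset",
    "default_config",
    "generate",
    "write_dataset",
    "recovery_experiment",
]


@dataclass(frozen=True)
class IndicatorSim:
    """Simulation parameters for one indicator.

    ``baseline_level`` (mu) is the comparison-arm level at the first
    study month, in the indicator's native unit; ``trend`` (tau) is the
    shared secular change per month; ``theta`` is the injected program
    effect expressed as the target %impact fraction; ``noise`` is
    "gaussian" (additive, sd ``sigma``, values clipped at 0) or
    "poisson" (counts with the series expectation as rate);
    ``missing_rate`` is the per-cell completely-at-random missingness
    probability.
    """

    indicator_id: str
    domain: Domain = Domain.SERVICE_USE
    polarity: Polarity = Polarity.HIGHER_BETTER
    baseline_level: float = 8.0
    trend: float = 0.05
    theta: float = 0.0
    noise: str = "gaussian"
    sigma: float = 0.1
    missing_rate: float = 0.0
    value_kind: str = "rate"

    def __post_init__(self) -> None:
        if self.baseline_level < 0:
            raise ValueError("baseline_level must be >= 0")
        if self.noise not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise == "gaussian" and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    n_pro_zones_per_province: int = 3
    n_non_zones_per_province: int = 28
    calendar: PhaseCalendar = field(default_factory=build_default_calendar)
    indicators: tuple[IndicatorSim, ...] = ()
    provinces: tuple[Province, ...] = (Province.KONGO_CENTRAL,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pro_zones_per_province < 1 or self.n_non_zones_per_province < 1:
            raise ValueError("each arm needs at least one zone per province")
        if not self.indicators:
            raise ValueError("at least one indicator is required")


@dataclass
class SimulatedDataset:
    observations: pd.DataFrame
    roster: list[ZoneRecord]
    registry: list[IndicatorDefinition]
    truth: pd.DataFrame  # indicator_id, theta, and the generator params


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-like default: both provinces with their program-arm sizes
    (3 and 7 zones) against 28/29 comparison zones, 75 months, and a
    spread of injected effects across the six domains at levels typical
    of the published monthly averages."""
    indicators = (
        IndicatorSim(
            "sim_supervision",
            Domain.SUPERVISION_MANAGEMENT,
            Polarity.HIGHER_BETTER,
            baseline_level=6.0,
            trend=0.05,
            theta=0.56,
            sigma=0.1,
            missing_rate=0.05,
        ),
        IndicatorSim(
            "sim_service_use",
            Domain.SERVICE_USE,
            Polarity.HIGHER_BETTER,
            baseline_level=8.0,
            trend=0.05,
            theta=0.25,
            sigma=0.1,
            missing_rate=0.05,
        ),
        IndicatorSim(
            "sim_attrition",
            Domain.NUTRITIONAL_HEALTH,
            Polarity.LOWER_BETTER,
            baseline_level=1.0,
            trend=0.02,
            theta=-0.7,
            sigma=0.05,
            missing_rate=0.05,
        ),
        IndicatorSim(
            "sim_vaccination",
            Domain.VACCINATION,
            Polarity.HIGHER_BETTER,
            baseline_level=5.0,
            trend=0.05,
            theta=0.45,
            sigma=0.1,
            missing_rate=0.05,
        ),
        IndicatorSim(
            "sim_anc_visits",
            Domain.REPRODUCTIVE_MATERNAL,
            Polarity.HIGHER_BETTER,
            baseline_level=8.0,
            trend=0.03,
            theta=0.0,
            sigma=0.1,
            missing_rate=0.05,
        ),
        IndicatorSim(
            "sim_child_deaths",
            Domain.NEWBORN_CHILD,
            Polarity.LOWER_BETTER,
            baseline_level=9.0,
            trend=0.04,
            noise="poisson",
            theta=-0.5,
            missing_rate=0.05,
        ),
    )
    return SyntheticConfig(
        n_pro_zones_per_province=3,
        n_non_zones_per_province=28,
        indicators=indicators,
        provinces=(Province.KONGO_CENTRAL, Province.ITURI),
        seed=seed,
    )


def _stream(seed: int, zone_id: str, indicator_id: str) -> np.random.Generator:
    """Independent stream per (zone, indicator), stable under roster growth."""
    key = (
        seed & 0x7FFFFFFF,
        zlib.crc32(zone_id.encode()),
        zlib.crc32(indicator_id.encode()),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def _expected_series(
    sim: IndicatorSim,
    arm: Arm,
    months: list[tuple[int, int]],
    t0: int,
    since_shift: float,
    since_months: frozenset[tuple[int, int]],
) -> np.ndarray:
    t = np.array([month_index(m) - t0 for m in months], dtype=float)
    mean = sim.baseline_level + sim.trend * t
    if arm == Arm.PRO_DS:
        in_since = np.array([m in since_months for m in months])
        mean = mean + since_shift * in_since
    return mean


def generate(config: SyntheticConfig) -> SimulatedDataset:
    """Generate a complete synthetic dataset; deterministic given seed.

    The program-arm shift for an indicator is
    theta * tau * (mean since-month index - mean before-month index),
    which makes the expected program-arm change (1 + theta) times the
    expected comparison-arm change under balanced complete data.
    """
    cal = config.calendar
    months = cal.months_in([p.phase_id for p in cal.phases])
    before_months = cal.months_in(BEFORE_SET)
    since_months = cal.months_in(SINCE_SET)
    t0 = month_index(cal.first_month)
    tbar_before = float(
        np.mean([month_index(m) - t0 for m in before_months])
    )
    tbar_since = float(np.mean([month_index(m) - t0 for m in since_months]))
    since_set = frozenset(since_months)

    roster: list[ZoneRecord] = []
    for prov in config.provinces:
        tag = "kc" if prov == Province.KONGO_CENTRAL else "it"
        for i in range(config.n_pro_zones_per_province):
            roster.append(
                ZoneRecord(f"{tag}_pro_{i + 1:02d}", prov, Arm.PRO_DS)
            )
        for i in range(config.n_non_zones_per_province):
            roster.append(
                ZoneRecord(f"{tag}_non_{i + 1:02d}", prov, Arm.NON_PRO_DS)
            )

    registry = [
        IndicatorDefinition(
            indicator_id=s.indicator_id,
            label=s.indicator_id.replace("_", " "),
            domain=s.domain,
            polarity=s.polarity,
            provinces=frozenset(config.provinces),
            value_kind=s.value_kind,
        )
        for s in config.indicators
    ]

    rows: list[tuple[str, str, int, int, float]] = []
    truth_rows = []
    for sim in config.indicators:
        # comparison-arm expected change between the two pooled windows
        delta_non = sim.trend * (tbar_since - tbar_before)
        shift = sim.theta * delta_non
        truth_rows.append(
            {
                "indicator_id": sim.indicator_id,
                "theta": sim.theta,
                "baseline_level": sim.baseline_level,
                "trend": sim.trend,
                "noise": sim.noise,
                "sigma": sim.sigma if sim.noise == "gaussian" else np.nan,
                "missing_rate": sim.missing_rate,
                "polarity": sim.polarity.value,
                "expected_delta_non": delta_non,
                "since_shift": shift,
            }
        )
        for zone in roster:
            rng = _stream(config.seed, zone.zone_id, sim.indicator_id)
            mean = _expected_series(
                sim, zone.arm, months, t0, shift, since_set
            )
            if sim.noise == "gaussian":
                values = mean + (
                    rng.standard_normal(len(months)) * sim.sigma
                    if sim.sigma > 0
                    else 0.0
                )
                values = np.clip(values, 0.0, None)
            else:
                if np.any(mean < 0):
                    raise ValueError(
                        f"{sim.indicator_id}: negative Poisson rate; "
                        "check baseline_level/trend/theta"
                    )
                values = rng.poisson(mean).astype(float)
            if sim.missing_rate > 0:
                mask = rng.random(len(months)) < sim.missing_rate
                values = values.astype(float)
                values[mask] = np.nan
            for m, v in zip(months, values):
                rows.append(
                    (zone.zone_id, sim.indicator_id, m[0], m[1], float(v))
                )

    obs = pd.DataFrame(
        rows, columns=["zone_id", "indicator_id", "year", "month", "value"]
    )
    return SimulatedDataset(
        observations=obs,
        roster=roster,
        registry=registry,
        truth=pd.DataFrame(truth_rows),
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> list[Path]:
    """Write observations/roster/registry in the ingest formats plus the
    ground-truth table; byte-identical for identical configs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": out_dir / "observations.csv",
        "roster": out_dir / "roster.csv",
        "registry": out_dir / "registry.csv",
        "truth": out_dir / "truth.csv",
    }
    write_observations(dataset.observations, paths["observations"])
    save_roster(dataset.roster, paths["roster"])
    save_registry(dataset.registry, paths["registry"])
    dataset.truth.to_csv(paths["truth"], index=False, lineterminator="\n")
    return list(paths.values())


def recovery_experiment(
    config: SyntheticConfig,
    n_replicates: int,
    estimator_config=None,
) -> pd.DataFrame:
    """Replicate generate -> estimate and report recovery per indicator.

    Each replicate re-generates the panel under a seed derived from the
    config seed and runs the full estimator on every indicator (first
    listed province).  Reports the mean and sd of the recovered %impact,
    the count of UNDEFINED replicates (never silently dropped), and the
    accuracy of the POSITIVE / NOT_POSITIVE call against the sign of the
    true theta combined with the indicator's polarity.
    """
    from .estimator import Classification, EstimatorConfig, evaluate_indicator

    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    est_cfg = estimator_config or EstimatorConfig()
    province = config.provinces[0]

    results: dict[str, list[float]] = {
        s.indicator_id: [] for s in config.indicators
    }
    n_undefined = {s.indicator_id: 0 for s in config.indicators}
    n_correct = {s.indicator_id: 0 for s in config.indicators}

    base = np.random.SeedSequence((config.seed & 0x7FFFFFFF, 0x5EED))
    rep_seeds = [int(s) for s in base.generate_state(n_replicates) >> 1]
    for rep_seed in rep_seeds:
        ds = generate(replace(config, seed=rep_seed))
        for sim in config.indicators:
            est = evaluate_indicator(
                ds.observations,
                sim.indicator_id,
                province,
                ds.roster,
                ds.registry,
                config.calendar,
                est_cfg,
            )
            if est.percent_impact is None:
                n_undefined[sim.indicator_id] += 1
                continue
            results[sim.indicator_id].append(est.percent_impact)
            if sim.theta == 0:
                expected = Classification.NO_CHANGE
            elif (sim.theta > 0) == (
                sim.polarity == Polarity.HIGHER_BETTER
            ):
                expected = Classification.POSITIVE
            else:
                expected = Classification.NOT_POSITIVE
            if est.classification == expected:
                n_correct[sim.indicator_id] += 1

    rows = []
    for sim in config.indicators:
        vals = np.asarray(results[sim.indicator_id], dtype=float)
        n_def = len(vals)
        rows.append(
            {
                "indicator_id": sim.indicator_id,
                "theta_true": sim.theta,
                "n_replicates": n_replicates,
                "n_defined": n_def,
                "n_undefined": n_undefined[sim.indicator_id],
                "theta_hat_mean": float(vals.mean()) if n_def else np.nan,
                "theta_hat_sd": (
                    float(vals.std(ddof=1)) if n_def > 1 else np.nan
                ),
                "bias": (
                    float(vals.mean() - sim.theta) if n_def else np.nan
                ),
                "classification_accuracy": (
                    n_correct[sim.indicator_id] / n_def if n_def else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
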