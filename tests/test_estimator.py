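import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddimpact import (
    Arm,
    Classification,
    EstimatorConfig,
    Polarity,
    Province,
    classify_effect,
    evaluate_indicator,
    interpret_impact,
    percent_impact,
    phase_mean,
    round_half_up,
)
from ddimpact.phases import BEFORE_SET, SINCE_SET

from conftest import make_obs
from oracle_dd import brute_impact, months_of

CFG = EstimatorConfig()


class TestPhaseMean:
    def test_arithmetic_mean_of_present_values(
        self, calendar, tiny_roster
    ):
        obs = make_obs(
            [("p1", "cov", 2016, 1, 2.0), ("p1", "cov", 2016, 2, 4.0)]
        )
        assert phase_mean(
            obs, "cov", Arm.PRO_DS, {"T_BEFORE"}, calendar, tiny_roster
        ) == pytest.approx(3.0)

    def test_all_missing_is_undefined(self, calendar, tiny_roster):
        obs = make_obs([("p1", "cov", 2016, 1, None)])
        assert (
            phase_mean(
                obs, "cov", Arm.PRO_DS, {"T_BEFORE"}, calendar, tiny_roster
            )
            is None
        )

    def test_pooled_equals_zone_mean_on_balanced_panel(
        self, calendar, tiny_roster
    ):
        obs = make_obs(
            [("p1", "cov", 2016, m, 1.0) for m in (1, 2, 3)]
            + [("p2", "cov", 2016, m, 3.0) for m in (1, 2, 3)]
        )
        for pooling in ("pooled", "zone_mean"):
            assert phase_mean(
                obs, "cov", Arm.PRO_DS, {"T_BEFORE"}, calendar,
                tiny_roster, pooling=pooling,
            ) == pytest.approx(2.0)

    def test_pooling_conventions_differ_on_unbalanced_months(
        self, calendar, tiny_roster
    ):
        # zone p1 contributes 3 months at level 1, zone p2 one month at 3
        obs = make_obs(
            [("p1", "cov", 2016, m, 1.0) for m in (1, 2, 3)]
            + [("p2", "cov", 2016, 1, 3.0)]
        )
        pooled = phase_mean(
            obs, "cov", Arm.PRO_DS, {"T_BEFORE"}, calendar, tiny_roster
        )
        zone_mean = phase_mean(
            obs, "cov", Arm.PRO_DS, {"T_BEFORE"}, calendar, tiny_roster,
            pooling="zone_mean",
        )
        assert pooled == pytest.approx(1.5)  # (1+1+1+3)/4
        assert zone_mean == pytest.approx(2.0)  # (1+3)/2

    def test_empty_phase_set_rejected(self, calendar, tiny_roster):
        with pytest.raises(ValueError):
            phase_mean(
                make_obs([]), "cov", Arm.PRO_DS, set(), calendar, tiny_roster
            )


class TestPercentImpact:
    @pytest.mark.parametrize(
        "means, expected",
        [
            ((8.3, 11.1, 7.9, 9.7), 0.56),  # committee meetings held
            ((7.4, 9.0, 7.8, 9.4), 0.00),  # folic acid third dose
            ((8.67, 10.50, 7.99, 9.04), 0.74),  # Pentavalent 1
            ((1.0, 2.0, 1.0, 2.0), 0.0),
        ],
    )
    def test_reproduces_published_rows_from_their_means(self, means, expected):
        dd, p, _ = percent_impact(*means)
        assert round_half_up(p, 2) == pytest.approx(expected)

    def test_identical_changes_give_zero_double_difference(self):
        dd, p, unstable = percent_impact(1.0, 2.0, 1.0, 2.0)
        assert dd == pytest.approx(0.0)
        assert p == pytest.approx(0.0)
        assert not unstable

    def test_zero_comparison_change_is_undefined_and_unstable(self):
        dd, p, unstable = percent_impact(0.5, 0.6, 0.2, 0.2)
        assert p is None and unstable
        assert dd == pytest.approx(0.1)

    def test_small_comparison_change_flagged_but_returned(self):
        _, p, unstable = percent_impact(1.0, 1.1, 1.0, 1.01)
        assert unstable and p == pytest.approx(0.1 / 0.01 - 1)

    def test_non_finite_input_is_hard_error(self):
        with pytest.raises(ValueError):
            percent_impact(float("nan"), 1.0, 1.0, 2.0)


class TestInterpretImpact:
    @pytest.mark.parametrize(
        "p, fold, literal",
        [
            (-0.70, -0.30, "0.3 times less"),
            (-1.89, -1.89, "1.89 times less"),
            (3.46, 3.46, "3.46 times more"),
            (0.0, 0.0, "No change"),
            (-0.02, -0.98, "0.98 times less"),
            (-0.15, -0.85, "0.85 times less"),
            (21.29, 21.29, "21.29 times more"),
            (1.20, 1.20, "1.2 times more"),
            (-19.40, -19.40, "19.4 times less"),
            (-1.0, -1.0, "1 times less"),
        ],
    )
    def test_fold_and_literal_follow_published_convention(
        self, p, fold, literal
    ):
        got_fold, got_literal = interpret_impact(p)
        assert got_fold == pytest.approx(fold)
        assert got_literal == literal

    def test_undefined_input_labelled(self):
        fold, literal = interpret_impact(None)
        assert fold is None
        assert literal == "undefined (unstable denominator)"

    def test_rounding_happens_before_interpretation(self):
        fold, literal = interpret_impact(0.0049)  # rounds to 0.00
        assert (fold, literal) == (0.0, "No change")
        fold, literal = interpret_impact(0.005)  # half-up to 0.01
        assert (fold, literal) == (0.01, "0.01 times more")


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "p, polarity, expected",
        [
            (-15.92, Polarity.LOWER_BETTER, Classification.POSITIVE),
            (0.45, Polarity.HIGHER_BETTER, Classification.POSITIVE),
            (-0.5, Polarity.HIGHER_BETTER, Classification.NOT_POSITIVE),
            (0.5, Polarity.LOWER_BETTER, Classification.NOT_POSITIVE),
            (0.00, Polarity.HIGHER_BETTER, Classification.NO_CHANGE),
            (0.00, Polarity.LOWER_BETTER, Classification.NO_CHANGE),
            (None, Polarity.HIGHER_BETTER, Classification.UNDEFINED),
        ],
    )
    def test_polarity_times_sign(self, p, polarity, expected):
        assert classify_effect(p, polarity) == expected

    def test_no_change_band_respects_rounding(self):
        assert (
            classify_effect(0.004, Polarity.HIGHER_BETTER)
            == Classification.NO_CHANGE
        )
        assert (
            classify_effect(0.006, Polarity.HIGHER_BETTER)
            == Classification.POSITIVE
        )


class TestEvaluateIndicator:
    def test_constant_panel_is_no_change(
        self, constant_panel, tiny_registry, tiny_roster, calendar
    ):
        est = evaluate_indicator(
            constant_panel, "cov", Province.KONGO_CENTRAL,
            tiny_roster, tiny_registry, calendar,
        )
        assert est.double_difference == pytest.approx(0.0)
        assert est.percent_impact is None  # comparison arm did not change
        assert est.classification == Classification.UNDEFINED
        assert est.unstable_denominator

    def test_trending_panel_recovers_injected_ratio(
        self, tiny_registry, tiny_roster, calendar
    ):
        # comparison arm: 1 + 0.1*t; program arm adds theta * comparison
        # change during the program window
        months = calendar.months_in([p.phase_id for p in calendar.phases])
        since = set(calendar.months_in(SINCE_SET))
        theta = 0.5
        t_since = [i for i, m in enumerate(months) if m in since]
        t_before = [i for i, m in enumerate(months) if m not in since]
        delta_non = 0.1 * (np.mean(t_since) - np.mean(t_before))
        rows = []
        for zone in ("p1", "p2", "c1", "c2"):
            for i, (y, m) in enumerate(months):
                value = 1.0 + 0.1 * i
                if zone.startswith("p") and (y, m) in since:
                    value += theta * delta_non
                rows.append((zone, "cov", y, m, value))
        est = evaluate_indicator(
            make_obs(rows), "cov", Province.KONGO_CENTRAL,
            tiny_roster, tiny_registry, calendar,
        )
        assert est.percent_impact == pytest.approx(theta, abs=1e-9)
        assert est.classification == Classification.POSITIVE

    def test_missing_arm_yields_undefined_with_note(
        self, tiny_registry, tiny_roster, calendar
    ):
        obs = make_obs([("p1", "cov", 2016, 1, 1.0)])
        est = evaluate_indicator(
            obs, "cov", Province.KONGO_CENTRAL,
            tiny_roster, tiny_registry, calendar,
        )
        assert est.classification == Classification.UNDEFINED
        assert est.literal == "undefined (no data)"
        assert "no present values" in est.note

    def test_arithmetic_identities_hold(
        self, tiny_registry, tiny_roster, calendar, rng=np.random.default_rng(7)
    ):
        months = calendar.months_in([p.phase_id for p in calendar.phases])
        rows = [
            (zone, "cov", y, m, float(rng.uniform(0, 10)))
            for zone in ("p1", "p2", "c1", "c2")
            for (y, m) in months
        ]
        est = evaluate_indicator(
            make_obs(rows), "cov", Province.KONGO_CENTRAL,
            tiny_roster, tiny_registry, calendar,
        )
        assert est.delta_pro == pytest.approx(
            est.ind_since_pro - est.ind_before_pro
        )
        assert est.delta_non == pytest.approx(
            est.ind_since_non - est.ind_before_non
        )
        assert est.double_difference == pytest.approx(
            est.delta_pro - est.delta_non
        )
        assert est.percent_impact == pytest.approx(
            est.delta_pro / est.delta_non - 1
        )


def random_panel(seed, n_zones=4, missing_rate=0.2):
    """Small random panel over a handful of months in each window."""
    rng = np.random.default_rng(seed)
    zones = [f"p{i}" for i in range(1, 1 + n_zones // 2)] + [
        f"c{i}" for i in range(1, 1 + n_zones - n_zones // 2)
    ]
    months = [(2016, 1), (2016, 2), (2017, 5), (2019, 3), (2021, 2), (2022, 1)]
    rows = []
    for zone in zones:
        for y, m in months:
            if rng.random() < missing_rate:
                value = None
            else:
                value = float(rng.uniform(0, 20))
            rows.append((zone, "cov", y, m, value))
    return make_obs(rows), zones


class TestOracleEquivalence:
    @pytest.mark.parametrize("pooling", ["pooled", "zone_mean"])
    def test_matches_brute_force_on_random_panels(
        self, calendar, tiny_registry, tiny_roster, pooling
    ):
        before = months_of(calendar, BEFORE_SET)
        since = months_of(calendar, SINCE_SET)
        cfg = EstimatorConfig(pooling=pooling)
        n_checked = 0
        for seed in range(100):
            obs, _ = random_panel(seed)
            records = [
                (r.zone_id, r.indicator_id, (int(r.year), int(r.month)),
                 None if pd.isna(r.value) else float(r.value))
                for r in obs.itertuples(index=False)
            ]
            dd_brute, p_brute = brute_impact(
                records, "cov", {"p1", "p2"}, {"c1", "c2"},
                before, since, pooling=pooling,
            )
            est = evaluate_indicator(
                obs, "cov", Province.KONGO_CENTRAL,
                tiny_roster, tiny_registry, calendar, cfg,
            )
            if dd_brute is None:
                assert est.double_difference is None
                continue
            assert est.double_difference == pytest.approx(
                dd_brute, abs=1e-12
            )
            if p_brute is None:
                assert est.percent_impact is None
            else:
                assert est.percent_impact == pytest.approx(
                    p_brute, abs=1e-12
                )
                n_checked += 1
        assert n_checked >= 50  # most random panels are fully comparable


means_strategy = st.floats(
    min_value=0.0, max_value=1e4, allow_nan=False, allow_infinity=False
)


class TestAlgebraicProperties:
    @given(
        bp=means_strategy, sp=means_strategy,
        bn=means_strategy, sn=means_strategy,
        c=st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance(self, bp, sp, bn, sn, c):
        """Multiplying every value by c > 0 rescales the double difference
        but leaves the ratio %impact unchanged."""
        dd, p, _ = percent_impact(bp, sp, bn, sn)
        dd_c, p_c, _ = percent_impact(bp * c, sp * c, bn * c, sn * c)
        assert dd_c == pytest.approx(dd * c, rel=1e-9, abs=1e-9)
        if p is not None and abs(sn - bn) * c >= CFG.denominator_epsilon:
            assert p_c == pytest.approx(p, rel=1e-6, abs=1e-6)

    @given(
        bp=means_strategy, sp=means_strategy,
        bn=means_strategy, sn=means_strategy,
        shift=st.floats(min_value=0, max_value=1e4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_translation_invariance(self, bp, sp, bn, sn, shift):
        """Adding a constant to every value changes neither the double
        difference nor the %impact."""
        if abs(sn - bn) < 1e-6:  # degenerate denominator: float
            return  # cancellation after shifting dominates
        dd, p, _ = percent_impact(bp, sp, bn, sn)
        dd_s, p_s, _ = percent_impact(
            bp + shift, sp + shift, bn + shift, sn + shift
        )
        assert dd_s == pytest.approx(dd, rel=1e-6, abs=1e-6)
        if p is not None and p_s is not None:
            assert p_s == pytest.approx(p, rel=1e-6, abs=1e-6)

    @given(
        bp=means_strategy, sp=means_strategy,
        bn=means_strategy, sn=means_strategy,
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_arm_swap_reciprocal_identity(self, bp, sp, bn, sn):
        """Swapping the arm labels inverts the change ratio:
        (1 + p_swapped) * (1 + p) = 1 whenever both are defined."""
        # restrict to non-degenerate changes: at denominators within float
        # noise of zero the product loses precision (and the estimator
        # flags such rows unstable anyway)
        if abs(sn - bn) < 1e-6 or abs(sp - bp) < 1e-6:
            return
        _, p, _ = percent_impact(bp, sp, bn, sn)
        _, p_swap, _ = percent_impact(bn, sn, bp, sp)
        if p is not None and p_swap is not None:
            assert (1 + p_swap) * (1 + p) == pytest.approx(
                1.0, rel=1e-6, abs=1e-6
            )


class TestPublishedRowReproduction:
    def test_every_usable_row_reproduces_at_its_recorded_level(
        self, reported_impacts, packaged_registry
    ):
        """Rows whose printed means reproduce the printed impact must match
        exactly after 2-decimal rounding; rows that evidently came from
        unrounded source data must still reproduce the direction and the
        polarity classification; rows with a zero comparison-arm change at
        printed precision must be flagged unstable."""
        registry = {d.indicator_id: d for d in packaged_registry}
        checked = {"exact": 0, "sign": 0, "unstable": 0}
        for row in reported_impacts.itertuples(index=False):
            if row.check in ("malformed", "none"):
                continue
            prov = Province(row.province)
            dd, p, unstable = percent_impact(
                row.ind_before_pro, row.ind_since_pro,
                row.ind_before_non, row.ind_since_non,
            )
            if row.check == "unstable":
                assert unstable, row.indicator_id
                checked["unstable"] += 1
                continue
            assert p is not None
            if row.check == "exact":
                assert round_half_up(p, 2) == pytest.approx(
                    row.printed_impact
                ), row.indicator_id
                fold, literal = interpret_impact(p)
                assert fold == pytest.approx(row.printed_fold), (
                    row.indicator_id
                )
                assert literal == row.printed_literal, row.indicator_id
                checked["exact"] += 1
            else:  # sign
                assert np.sign(p) == np.sign(row.printed_impact), (
                    row.indicator_id
                )
                polarity = registry[row.indicator_id].polarity_for(prov)
                expected = classify_effect(row.printed_impact, polarity)
                assert classify_effect(p, polarity) == expected, (
                    row.indicator_id
                )
                checked["sign"] += 1
        # fixture composition is stable
        assert checked == {"exact": 18, "sign": 62, "unstable": 7}

    def test_interpretation_matches_print_wherever_impact_matches(
        self, reported_impacts
    ):
        """The fold/literal columns are a pure function of the printed
        impact: feeding each printed impact back through the interpreter
        reproduces the printed fold and literal on every usable row."""
        for row in reported_impacts.itertuples(index=False):
            if row.check == "malformed":
                continue
            fold, literal = interpret_impact(row.printed_impact)
            assert fold == pytest.approx(row.printed_fold), row.indicator_id
            assert literal == row.printed_literal, row.indicator_id
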