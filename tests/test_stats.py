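"""Contingency, rank and survival statistics."""

import pandas as pd
import pytest
from scipy import stats as sps

from umglyco.stats import (
    SurvivalRecord,
    associate,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    median_split,
    pearson_chi_square,
)
from umglyco.util import format_p, round_half_away


class TestPearsonChiSquare:
    def test_uniform_table_is_independent(self):
        chi2, p = pearson_chi_square([[5, 5], [5, 5]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_uncorrected_statistic_on_2x2(self):
        chi2, p = pearson_chi_square([[12, 4], [3, 11]])
        assert chi2 == pytest.approx(8.5714, abs=1e-4)
        assert p == pytest.approx(0.0034, abs=1e-4)

    def test_small_expected_cells_warn(self):
        with pytest.warns(UserWarning, match="expected count"):
            pearson_chi_square([[1, 1], [13, 14]])

    def test_closed_form_2x2(self, rng):
        # chi2 = N (ad - bc)^2 / (r1 r2 c1 c2)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 30, 4)
            chi2, _ = pearson_chi_square([[a, b], [c, d]])
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(expected)

    def test_permutation_and_transpose_invariance(self, rng):
        t = rng.integers(1, 40, (3, 4))
        chi2, p = pearson_chi_square(t)
        assert pearson_chi_square(t[::-1])[0] == pytest.approx(chi2)
        assert pearson_chi_square(t[:, ::-1])[0] == pytest.approx(chi2)
        assert pearson_chi_square(t.T)[0] == pytest.approx(chi2)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="empty row or column"):
            pearson_chi_square([[0, 0], [3, 4]])


class TestKruskalWallis:
    def test_identical_groups_no_evidence(self):
        h, p = kruskal_wallis([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        assert h == 0.0 and p == 1.0

    def test_two_groups_equal_mwu_normal_approx_squared(self, rng):
        from umglyco.expression import mwu_test

        a = rng.normal(size=30)
        b = rng.normal(size=25)
        h, p_kw = kruskal_wallis([a, b])
        z = sps.norm.isf(mwu_test(a, b) / 2)
        assert h == pytest.approx(z**2, rel=1e-6)
        assert p_kw == pytest.approx(mwu_test(a, b), rel=1e-6)

    def test_fully_separated_small_groups(self):
        # direct rank computation: H = 12/(6*7) * (9+49+121)/2 - 21
        h, _ = kruskal_wallis([[1, 2], [10, 11], [20, 21]])
        assert h == pytest.approx(4.5714, abs=1e-4)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


def _rec(i, t, e, g):
    return SurvivalRecord(str(i), t, e, g)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curves = km_estimate([_rec(i, t, False, "high") for i, t in enumerate([3, 5, 9])])
        assert (curves["high"]["survival"] == 1.0).all()

    def test_two_events_no_censoring(self):
        curves = km_estimate([_rec(0, 1.0, True, "g"), _rec(1, 2.0, True, "g")])
        sf = curves["g"].set_index("time")["survival"]
        assert sf[1.0] == pytest.approx(0.5)
        assert sf[2.0] == pytest.approx(0.0)

    def test_hand_computed_product_limit_with_censoring(self):
        # events at 2 (2 of 5 at risk... one event), censor at 3, event at 4, censor at 6
        recs = [
            _rec(0, 2.0, True, "g"),
            _rec(1, 3.0, False, "g"),
            _rec(2, 4.0, True, "g"),
            _rec(3, 4.0, True, "g"),
            _rec(4, 6.0, False, "g"),
        ]
        sf = km_estimate(recs)["g"].set_index("time")["survival"]
        assert sf[2.0] == pytest.approx(4 / 5)
        assert sf[4.0] == pytest.approx(4 / 5 * 1 / 3)
        assert sf[6.0] == pytest.approx(4 / 5 * 1 / 3)

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10, 40).round(2)
        recs = [_rec(i, t, True, "g") for i, t in enumerate(times)]
        sf = km_estimate(recs)["g"]
        for t, s in zip(sf["time"], sf["survival"]):
            assert s == pytest.approx((times > t).mean())


class TestLogRank:
    def test_identical_groups(self):
        recs = [_rec(i, t, True, "a") for i, t in enumerate([1, 2, 3])] + [
            _rec(10 + i, t, True, "b") for i, t in enumerate([1, 2, 3])
        ]
        stat, p = logrank_test(recs)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_label_swap(self, rng):
        recs = [
            _rec(i, float(t), bool(e), "a" if i < 20 else "b")
            for i, (t, e) in enumerate(
                zip(rng.exponential(10, 40), rng.random(40) < 0.8)
            )
        ]
        swapped = [
            SurvivalRecord(r.subject, r.time, r.event, "b" if r.group == "a" else "a")
            for r in recs
        ]
        assert logrank_test(recs)[1] == pytest.approx(logrank_test(swapped)[1])

    def test_extreme_separation_matches_hypergeometric_accumulation(self):
        # all events early in one group: accumulate O-E and Var from the
        # per-event-time 2x2 tables by hand and compare the chi-square
        times_a = [1.0, 2.0, 3.0]
        times_b = [10.0, 11.0, 12.0]
        recs = [_rec(i, t, True, "a") for i, t in enumerate(times_a)] + [
            _rec(10 + i, t, True, "b") for i, t in enumerate(times_b)
        ]
        o_minus_e, var = 0.0, 0.0
        at_risk = [(3, 3), (2, 3), (1, 3), (0, 3), (0, 2), (0, 1)]
        for (na, nb) in at_risk:
            n = na + nb
            if na == 0:
                ea = 0.0
                v = 0.0
            else:
                ea = na / n
                v = na * nb * (n - 1) / (n**2 * (n - 1)) if n > 1 else 0.0
            observed_a = 1.0 if na > 0 and (na, nb) in [(3, 3), (2, 3), (1, 3)] else 0.0
            o_minus_e += observed_a - ea
            var += v
        expected_chi2 = o_minus_e**2 / var
        stat, _ = logrank_test(recs)
        assert stat == pytest.approx(expected_chi2, rel=1e-6)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([_rec(0, 1.0, True, "a")])


class TestMedianSplit:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4], ["low", "low", "high", "high"]),
            ([5, 5, 5], ["high", "high", "high"]),
            ([1, 2, 3], ["low", "high", "high"]),
        ],
    )
    def test_examples(self, values, expected):
        assert median_split(pd.Series(values)).tolist() == expected

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([1.0]))


class TestAssociate:
    def _clinical(self):
        return pd.DataFrame(
            {
                "group": ["high"] * 5 + ["low"] * 5,
                "age": [70, 72, 68, 75, 71, 60, 62, 59, 61, 64],
                "sex": ["F", "M", "F", "M", "F", "M", "M", "F", "M", "M"],
                "constant": [1] * 10,
                "with_missing": [1.0, 2.0, None, 4.0, 5.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )

    def test_dispatch_and_display(self):
        report = associate(
            self._clinical(),
            "group",
            {"age": "numeric", "sex": "categorical", "constant": "numeric"},
        ).set_index("variable")
        assert report.loc["age", "test"] == "mann_whitney"
        assert report.loc["sex", "test"] == "pearson_chi_square"
        assert report.loc["constant", "test"] == "skipped_constant"
        p = report.loc["age", "p"]
        assert report.loc["age", "p_display"] == format_p(p)

    def test_missing_values_dropped_with_count(self):
        report = associate(
            self._clinical(), "group", {"with_missing": "numeric"}
        ).set_index("variable")
        assert report.loc["with_missing", "n"] == 9

    def test_multilevel_grouping_uses_kruskal(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                "x": list(range(12)),
            }
        )
        report = associate(df, "group", {"x": "numeric"})
        assert report.loc[0, "test"] == "kruskal_wallis"

    def test_unknown_type_errors(self):
        with pytest.raises(ValueError, match="unknown declared type"):
            associate(self._clinical(), "group", {"age": "fancy"})


def test_display_rounding_half_away_from_zero():
    assert round_half_away(0.0034) == 0.0
    assert format_p(0.0034) == "0.00"
    assert round_half_away(0.005) == 0.01
    assert round_half_away(-2.2974) == -2.30
    assert format_p(0.4643) == "0.46"
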