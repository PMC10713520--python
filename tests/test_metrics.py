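"""Aggregation, the log-log excess model, and the statistical toolbox."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geobiblio import (
    aggregate_by_unit,
    bh_adjust,
    compare_slopes,
    compute_excess,
    fit_loglog,
    geolocate_records,
    group_compare,
    iri_literal,
    journal_country_composition,
    population_normalize,
    spearman_corr,
    yearly_trend,
)
from geobiblio.geolocation import CountryInfo

from conftest import make_records


def _toy_rows(units, articles, citations):
    return pd.DataFrame({"unit": units, "n_articles": articles, "total_citations": citations})


class TestAggregate:
    def test_multi_country_record_counts_once_per_country(self, gazetteer):
        rs = make_records(
            [
                ("BMJ", 2015, 10, ["A, Boston, USA", "B, London, UK"]),
                ("BMJ", 2016, 4, ["C, Boston, USA", "D, New York, USA"]),
            ]
        )
        geos = geolocate_records(rs, gazetteer)
        rows = aggregate_by_unit(rs, geos, min_articles=1).set_index("unit")
        # record 0 counts once in each country with full citations;
        # record 1 has two USA addresses but counts once in USA
        assert rows.loc["USA", "n_articles"] == 2
        assert rows.loc["USA", "total_citations"] == 14
        assert rows.loc["UK", "n_articles"] == 1 and rows.loc["UK", "total_citations"] == 10

    def test_city_level_keeps_same_named_cities_apart(self, gazetteer):
        rs = make_records(
            [
                ("BMJ", 2015, 1, ["X, London, UK"]),
                ("BMJ", 2015, 1, ["Y, London, Ontario, Canada"]),
            ]
        )
        rows = aggregate_by_unit(rs, geolocate_records(rs, gazetteer), level="city", min_articles=1)
        assert set(rows["unit"]) == {("London", "UK"), ("London", "Canada")}

    def test_threshold_drops_small_units_and_reports_coverage(self, gazetteer):
        rs = make_records(
            [("BMJ", 2015, 1, ["A, Boston, USA"])] * 12 + [("BMJ", 2015, 1, ["B, Oslo, Norway"])] * 3
        )
        rows = aggregate_by_unit(rs, geolocate_records(rs, gazetteer), min_articles=10)
        assert list(rows["unit"]) == ["USA"]
        assert rows.attrs["coverage"] == pytest.approx(12 / 15)

    def test_matches_generator_bookkeeping(self, small_corpus, gazetteer):
        rs, _, truth, _ = small_corpus
        rows = aggregate_by_unit(rs, geolocate_records(rs, gazetteer), min_articles=1)
        got = dict(zip(rows["unit"], rows["n_articles"]))
        assert got == truth["per_country"]

    def test_unknown_attribution_rule(self, small_corpus, gazetteer):
        rs = small_corpus[0]
        with pytest.raises(ValueError):
            aggregate_by_unit(rs, {}, attribution="fractional")


class TestLogLogFit:
    def test_three_point_fit_matches_closed_form_ols(self):
        rows = _toy_rows(["a", "b", "c"], [10, 100, 1000], [100, 1000, 5000])
        fit = fit_loglog(rows)
        x = np.log10([100, 1000, 5000.0])
        y = np.log10([10, 100, 1000.0])
        n = 3
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        intercept = y.mean() - slope * x.mean()
        r2 = ((x * y).mean() - x.mean() * y.mean()) ** 2 / (x.var() * y.var())
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)

    def test_collinear_points_have_unit_r_squared(self):
        rows = _toy_rows(["a", "b", "c"], [10, 100, 1000], [50, 500, 5000])
        assert fit_loglog(rows).r_squared == pytest.approx(1.0)

    def test_r_squared_direction_independent(self):
        rows = _toy_rows(["a", "b", "c", "d"], [10, 80, 300, 1000], [200, 900, 4000, 20000])
        f1 = fit_loglog(rows, direction="articles_on_citations")
        f2 = fit_loglog(rows, direction="citations_on_articles")
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-12)

    def test_residuals_sum_to_zero(self):
        rows = _toy_rows(list("abcde"), [10, 80, 300, 1000, 44], [200, 900, 4000, 20000, 800])
        assert fit_loglog(rows).residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_zero_counts_rejected_with_threshold_hint(self):
        rows = _toy_rows(["a", "b", "c"], [10, 0, 5], [100, 10, 50])
        with pytest.raises(ValueError, match="threshold"):
            fit_loglog(rows)

    def test_too_few_units(self):
        with pytest.raises(ValueError):
            fit_loglog(_toy_rows(["a", "b"], [10, 100], [100, 1000]))


class TestExcess:
    def test_unit_on_regression_line_has_zero_excess(self):
        # construct perfectly collinear data: every unit lies on the line
        rows = _toy_rows(["a", "b", "c"], [10, 100, 1000], [50, 500, 5000])
        excess = compute_excess(rows, fit_loglog(rows))
        assert excess["excess_articles"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_scaling_all_citations_leaves_excess_unchanged(self):
        rows = _toy_rows(list("abcd"), [10, 80, 300, 1000], [200, 900, 4000, 20000])
        base = compute_excess(rows, fit_loglog(rows))["excess_articles"]
        scaled_rows = rows.assign(total_citations=rows["total_citations"] * 7.5)
        scaled = compute_excess(scaled_rows, fit_loglog(scaled_rows))["excess_articles"]
        assert np.allclose(base, scaled)

    def test_excess_pct_invariant_under_row_reordering(self):
        rows = _toy_rows(list("abcd"), [10, 80, 300, 1000], [200, 900, 4000, 20000])
        fwd = compute_excess(rows, fit_loglog(rows)).set_index("unit")["excess_pct"]
        rev_rows = rows.iloc[::-1].reset_index(drop=True)
        rev = compute_excess(rev_rows, fit_loglog(rev_rows)).set_index("unit")["excess_pct"]
        assert np.allclose(fwd.sort_index(), rev.sort_index())

    def test_unit_absent_from_fit_rejected(self):
        rows = _toy_rows(list("abcd"), [10, 80, 300, 1000], [200, 900, 4000, 20000])
        fit = fit_loglog(rows.iloc[:3])
        with pytest.raises(ValueError, match="d"):
            compute_excess(rows, fit)

    def test_flag_matches_pct_threshold(self):
        rows = _toy_rows(list("abcde"), [10, 80, 300, 1000, 44], [200, 900, 4000, 20000, 800])
        excess = compute_excess(rows, fit_loglog(rows))
        assert (excess["flag_ge10pct"] == (excess["excess_pct"].abs() >= 10)).all()


class TestIRI:
    @pytest.mark.parametrize(
        "articles,citations,expected",
        [(100, 1000, 2 / 3), (1000, 1000, 1.0), (50, 2000, np.log10(50) / np.log10(2000))],
    )
    def test_literal_index(self, articles, citations, expected):
        assert iri_literal(articles, citations) == pytest.approx(expected, abs=1e-12)

    def test_counts_of_one_rejected(self):
        with pytest.raises(ValueError):
            iri_literal(1, 100)


class TestPopulationNormalize:
    def test_articles_per_million(self):
        rows = _toy_rows(["Denmark"], [182], [6600])
        info = [CountryInfo("Denmark", "Europe", 5.85e6)]
        out = population_normalize(rows, info)
        assert out["articles_per_million"][0] == pytest.approx(31.1, abs=0.05)

    def test_missing_population_flagged(self):
        rows = _toy_rows(["Atlantis"], [50], [100])
        out = population_normalize(rows, [])
        assert out["population_missing"].all()
        assert np.isnan(out["articles_per_million"][0])


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3, 4], [40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho, _ = spearman_corr(x, y)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_matches_hand_oracle_and_is_monotone(self, pvals):
        adj = bh_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals)
        ranked = np.asarray(pvals)[order] * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        assert np.allclose(adj[order], hand, atol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-12).all()


class TestTrends:
    def _records_with_counts(self, counts_by_year):
        rows = []
        for year, k in counts_by_year.items():
            rows += [("BMJ", year, 0, ["A, Boston, USA"])] * k
        return make_records(rows)

    def test_exact_linear_decline(self, gazetteer):
        rs = self._records_with_counts({2010 + i: 20 - 2 * i for i in range(5)})
        tf = yearly_trend(rs, geolocate_records(rs, gazetteer), "USA")
        assert tf.slope == pytest.approx(-2.0, abs=1e-9)

    def test_constant_series_zero_slope(self, gazetteer):
        rs = self._records_with_counts({y: 5 for y in range(2010, 2015)})
        tf = yearly_trend(rs, geolocate_records(rs, gazetteer), "USA")
        assert tf.slope == pytest.approx(0.0, abs=1e-9)

    def test_gap_years_count_zero_articles(self, gazetteer):
        rs = self._records_with_counts({2010: 4, 2012: 4})
        tf = yearly_trend(rs, geolocate_records(rs, gazetteer), "USA")
        assert tf.n_years == 3 and tf.series[2011] == 0

    def test_single_year_rejected(self, gazetteer):
        rs = self._records_with_counts({2015: 5})
        with pytest.raises(ValueError):
            yearly_trend(rs, geolocate_records(rs, gazetteer), "USA")


class TestCompareSlopes:
    def test_constant_shift_gives_zero_interaction(self):
        t = np.arange(2010, 2020, dtype=float)
        a = pd.Series(3.0 * t - 6000.0, index=t)
        b = a + 42.0
        est, _ = compare_slopes(a, b)
        assert est == pytest.approx(0.0, abs=1e-8)

    def test_opposite_slopes_detected(self):
        rng = np.random.default_rng(3)
        t = np.arange(2010, 2020, dtype=float)
        a = pd.Series(2.0 * t - 4000 + rng.normal(0, 0.5, 10), index=t)
        b = pd.Series(-2.0 * t + 4100 + rng.normal(0, 0.5, 10), index=t)
        est, p = compare_slopes(a, b)
        assert p < 1e-3 and est == pytest.approx(-4.0, abs=0.5)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(12345)
        t = np.arange(10, dtype=float)
        hits = 0
        reps = 500
        for _ in range(reps):
            a = pd.Series(1.0 * t + rng.normal(0, 1, 10), index=t)
            b = pd.Series(1.0 * t + rng.normal(0, 1, 10), index=t)
            hits += compare_slopes(a, b)[1] < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_degenerate_series_rejected(self):
        t = np.arange(5, dtype=float)
        a = pd.Series(np.zeros(5), index=t)
        with pytest.raises(ValueError):
            compare_slopes(a, a)


class TestGroupCompare:
    def test_identical_groups_have_zero_h(self):
        res = group_compare({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res["statistic"][0] == 0.0 and res["pvalue"][0] == 1.0

    def test_wilcoxon_two_groups(self):
        res = group_compare({"a": [1, 2, 3, 4], "b": [10, 11, 12, 13]}, test="wilcoxon")
        assert res["pvalue"][0] < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_compare({"a": [1.0], "b": []})

    def test_wilcoxon_needs_exactly_two(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1], "b": [2], "c": [3]}, test="wilcoxon")


class TestComposition:
    def test_identical_composition_not_flagged(self, gazetteer):
        # two journals with the same country mix each year: H = 0 everywhere
        rows = []
        for journal in ("BMJ", "Lancet"):
            for year in range(2010, 2020):
                rows += [(journal, year, 0, ["A, Boston, USA"])] * 6
                rows += [(journal, year, 0, ["B, London, UK"])] * 4
        rs = make_records(rows)
        prop, tests = journal_country_composition(rs, geolocate_records(rs, gazetteer))
        assert not tests["flagged"].any()
        assert prop.loc["BMJ", "USA"] == pytest.approx(0.6)

    def test_home_country_affinity_flagged(self, small_corpus, gazetteer):
        rs = small_corpus[0]  # generated with 5x home-journal affinity
        _, tests = journal_country_composition(rs, geolocate_records(rs, gazetteer))
        flagged = set(tests[tests["flagged"]]["country"])
        assert {"USA", "UK"} <= flagged

    def test_single_journal_rejected(self, gazetteer):
        rows = [("BMJ", 2010, 0, ["A, Boston, USA"])] * 30
        rs = make_records(rows)
        with pytest.raises(ValueError):
            journal_country_composition(rs, geolocate_records(rs, gazetteer))
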