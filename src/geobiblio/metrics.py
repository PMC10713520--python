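"""Publication-citation aggregates, the log-log excess model, and group tests.

The central model: across publishing units (countries or cities),
log10(citations) is very nearly linear in log10(publications).  Fitting that
line by OLS and asking how many articles a unit "should" have published
given its accumulated citations yields a signed per-unit publication excess
(observed - expected) — the operational form of the International Research
Impact (IRI) index.  Units whose |excess| is at least 10% of their observed
output are flagged as over-/under-represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .geolocation import CountryInfo, GeoLocation
from .records import RecordSet, citations_per_year

__all__ = [
    "aggregate_by_unit",
    "LogLogFit",
    "fit_loglog",
    "compute_excess",
    "iri_literal",
    "population_normalize",
    "spearman_corr",
    "bh_adjust",
    "TrendFit",
    "yearly_trend",
    "compare_slopes",
    "group_compare",
    "journal_country_composition",
]

DEFAULT_MIN_ARTICLES = 10
DEFAULT_FLAG_PCT = 10.0


def _units_of_record(geos: Sequence[GeoLocation], level: str) -> set:
    units = set()
    for g in geos:
        if g.resolution == "unresolved" or g.country is None:
            continue
        if level == "country":
            units.add(g.country)
        elif level == "city":
            if g.resolution == "city":
                units.add((g.city, g.country))
        else:
            raise ValueError(f"unknown aggregation level {level!r}")
    return units


def aggregate_by_unit(
    rs: RecordSet,
    geos: Mapping[str, Sequence[GeoLocation]],
    level: str = "country",
    min_articles: int = DEFAULT_MIN_ARTICLES,
    reference_year: int | None = None,
    attribution: str = "once-per-unit",
) -> pd.DataFrame:
    """Aggregate article and citation counts per country or (city, country).

    Attribution: a record contributes one article and its full citation
    count to each *distinct* unit among its addresses — two addresses in
    the same country count once there; addresses in two countries count
    once in each (so country totals can exceed the article total).  Units
    with fewer than ``min_articles`` articles are dropped; the retained
    coverage fraction is stored in ``DataFrame.attrs``.
    """
    if attribution != "once-per-unit":
        raise ValueError(f"unknown attribution rule {attribution!r}")
    rows: dict = {}
    n_attributed = 0
    for rec in rs:
        units = _units_of_record(geos.get(rec.record_id, ()), level)
        if units:
            n_attributed += 1
        for u in units:
            agg = rows.setdefault(u, {"n_articles": 0, "total_citations": 0, "cpy": []})
            agg["n_articles"] += 1
            agg["total_citations"] += rec.total_citations
            if reference_year is not None:
                agg["cpy"].append(
                    citations_per_year(rec.total_citations, rec.year, reference_year)
                )
    out = pd.DataFrame(
        {
            "unit": list(rows),
            "n_articles": [v["n_articles"] for v in rows.values()],
            "total_citations": [v["total_citations"] for v in rows.values()],
            "citations_per_year_median": [
                float(np.median(v["cpy"])) if v["cpy"] else np.nan for v in rows.values()
            ],
        }
    ).sort_values("n_articles", ascending=False, kind="stable").reset_index(drop=True)
    total_articles = int(out["n_articles"].sum())
    out = out[out["n_articles"] >= min_articles].reset_index(drop=True)
    kept_articles = int(out["n_articles"].sum())
    out.attrs["level"] = level
    out.attrs["min_articles"] = min_articles
    out.attrs["attribution"] = attribution
    out.attrs["coverage"] = kept_articles / total_articles if total_articles else float("nan")
    out.attrs["n_records_attributed"] = n_attributed
    return out


@dataclass(frozen=True)
class LogLogFit:
    """OLS fit between log10 article and log10 citation counts."""

    slope: float
    intercept: float
    r_squared: float
    direction: str  # "articles_on_citations" or "citations_on_articles"
    residuals: pd.Series = field(repr=False)

    def predict_log_articles(self, total_citations: np.ndarray | float) -> np.ndarray:
        """Expected log10 article count given accumulated citations."""
        lc = np.log10(np.asarray(total_citations, dtype=float))
        if self.direction == "articles_on_citations":
            return self.intercept + self.slope * lc
        # invert the citations-on-articles line
        return (lc - self.intercept) / self.slope


def fit_loglog(rows: pd.DataFrame, direction: str = "articles_on_citations") -> LogLogFit:
    """OLS on (log10 n_articles, log10 total_citations) across units.

    R-squared equals the squared Pearson correlation of the two log columns
    and is therefore identical in both directions.
    """
    if direction not in ("articles_on_citations", "citations_on_articles"):
        raise ValueError(f"unknown regression direction {direction!r}")
    if len(rows) < 3:
        raise ValueError("need at least 3 units to fit the log-log relation")
    if (rows["n_articles"] <= 0).any() or (rows["total_citations"] <= 0).any():
        raise ValueError(
            "zero article or citation counts: apply the minimum-articles "
            "inclusion threshold before fitting"
        )
    la = np.log10(rows["n_articles"].to_numpy(dtype=float))
    lc = np.log10(rows["total_citations"].to_numpy(dtype=float))
    y, x = (la, lc) if direction == "articles_on_citations" else (lc, la)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    r2 = float(np.corrcoef(la, lc)[0, 1] ** 2)
    resid = pd.Series(y - fitted, index=rows["unit"].to_numpy(), name="residual")
    return LogLogFit(float(slope), float(intercept), r2, direction, resid)


def compute_excess(
    rows: pd.DataFrame, fit: LogLogFit, flag_pct: float = DEFAULT_FLAG_PCT
) -> pd.DataFrame:
    """Per-unit expected article count and signed publication excess.

    ``expected`` is the fitted article count at the unit's citations;
    ``excess = observed - expected``; ``excess_pct`` is relative to the
    observed count, so a unit on the line has excess 0.
    """
    missing = set(rows["unit"]) - set(fit.residuals.index)
    if missing:
        raise ValueError(f"units absent from the fit: {sorted(map(str, missing))}")
    expected = 10.0 ** fit.predict_log_articles(rows["total_citations"].to_numpy(float))
    out = rows[["unit", "n_articles", "total_citations"]].copy()
    out["expected_articles"] = expected
    out["excess_articles"] = out["n_articles"] - expected
    out["excess_pct"] = 100.0 * out["excess_articles"] / out["n_articles"]
    out["flag_ge10pct"] = out["excess_pct"].abs() >= flag_pct
    out.attrs["direction"] = fit.direction
    out.attrs["flag_pct"] = flag_pct
    return out


def iri_literal(n_articles: int, total_citations: int) -> float:
    """log10(publications) / log10(citations) for one unit.

    The literal index form; the regression residual form above is what
    drives excess/deficit estimates.
    """
    if n_articles <= 1 or total_citations <= 1:
        raise ValueError("iri_literal requires counts > 1 (log10 must be positive)")
    return float(np.log10(n_articles) / np.log10(total_citations))


def population_normalize(rows: pd.DataFrame, info: Iterable[CountryInfo]) -> pd.DataFrame:
    """Attach articles-per-million-persons; missing populations are flagged."""
    pop = {ci.country: ci.population for ci in info}
    out = rows.copy()
    populations = out["unit"].map(lambda u: pop.get(u))
    out["population"] = populations.astype(float)
    out["articles_per_million"] = out["n_articles"] / (out["population"] / 1e6)
    out["population_missing"] = populations.isna()
    return out


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with its t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_corr needs two equal-length sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass(frozen=True)
class TrendFit:
    unit: object
    value: str
    slope: float
    intercept: float
    n_years: int
    series: pd.Series = field(repr=False)


def _yearly_series(
    rs: RecordSet,
    geos: Mapping[str, Sequence[GeoLocation]],
    unit,
    level: str,
    value: str,
    reference_year: int | None,
) -> pd.Series:
    per_year: dict[int, list[int]] = {}
    for rec in rs:
        if unit in _units_of_record(geos.get(rec.record_id, ()), level):
            per_year.setdefault(rec.year, []).append(rec.total_citations)
    if value == "article_count":
        years = range(min(per_year), max(per_year) + 1) if per_year else []
        return pd.Series({y: len(per_year.get(y, [])) for y in years}, dtype=float)
    if value == "citations_per_article":
        ref = reference_year if reference_year is not None else max(per_year, default=0)
        return pd.Series(
            {
                y: float(np.mean([citations_per_year(c, y, ref) for c in cs]))
                for y, cs in sorted(per_year.items())
            },
            dtype=float,
        )
    raise ValueError(f"unknown trend value {value!r}")


def yearly_trend(
    rs: RecordSet,
    geos: Mapping[str, Sequence[GeoLocation]],
    unit,
    value: str = "article_count",
    level: str = "country",
    reference_year: int | None = None,
) -> TrendFit:
    """OLS slope of a unit's yearly article counts or citation rates.

    Years without articles count 0 in the article series and are omitted
    from the citation-rate series.
    """
    series = _yearly_series(rs, geos, unit, level, value, reference_year)
    if len(series) < 2:
        raise ValueError(f"unit {unit!r} has fewer than 2 years of data")
    slope, intercept = np.polyfit(series.index.to_numpy(float), series.to_numpy(), 1)
    return TrendFit(unit, value, float(slope), float(intercept), len(series), series)


def compare_slopes(series_a: pd.Series, series_b: pd.Series) -> tuple[float, float]:
    """Test equality of two regression slopes via the interaction term.

    Pools both (time, value) series into one OLS with a group indicator and
    a group x time interaction; returns (interaction estimate, two-sided
    t-test p-value of the interaction).
    """
    if len(series_a) < 3 or len(series_b) < 3:
        raise ValueError("both series need at least 3 points")
    t = np.concatenate([series_a.index.to_numpy(float), series_b.index.to_numpy(float)])
    y = np.concatenate([series_a.to_numpy(float), series_b.to_numpy(float)])
    g = np.concatenate([np.zeros(len(series_a)), np.ones(len(series_b))])
    X = sm.add_constant(np.column_stack([t, g, t * g]))
    res = sm.OLS(y, X).fit()
    if res.df_resid <= 0 or not np.isfinite(res.bse[3]) or res.bse[3] == 0:
        raise ValueError("degenerate series: interaction standard error is zero")
    return float(res.params[3]), float(res.pvalues[3])


def group_compare(
    values_by_group: Mapping[object, Sequence[float]],
    test: str = "kruskal_wallis",
    adjust: str = "none",
) -> pd.DataFrame:
    """Rank-based comparison of two or more groups.

    Two groups with ``test="wilcoxon"`` runs the unpaired two-sided rank-sum
    (Mann-Whitney) test; ``test="kruskal_wallis"`` handles any number of
    groups.  With ``adjust="BH"`` the (single-row) p-value column is passed
    through Benjamini-Hochberg for symmetry with multi-family callers.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        empty = [k for k, v in groups.items() if len(v) == 0]
        raise ValueError(f"empty group(s): {empty}")
    samples = list(groups.values())
    if test == "wilcoxon":
        if len(samples) != 2:
            raise ValueError("wilcoxon rank-sum compares exactly 2 groups")
        stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif test == "kruskal_wallis":
        if all(np.array_equal(samples[0], s) for s in samples[1:]):
            stat, p = 0.0, 1.0  # identical groups: H = 0 by definition
        else:
            stat, p = sps.kruskal(*samples)
    else:
        raise ValueError(f"unknown test {test!r}")
    out = pd.DataFrame({"test": [test], "statistic": [float(stat)], "pvalue": [float(p)]})
    out["pvalue_adj"] = bh_adjust(out["pvalue"]) if adjust == "BH" else out["pvalue"]
    return out


def journal_country_composition(
    rs: RecordSet,
    geos: Mapping[str, Sequence[GeoLocation]],
    min_articles: int = DEFAULT_MIN_ARTICLES,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Journal x country composition with per-country Kruskal-Wallis tests.

    Returns ``(proportions, tests)``.  ``proportions[j, c]`` is the fraction
    of journal *j*'s articles with a corresponding author in country *c*.
    For each retained country, the yearly proportions of each journal's
    output from that country are compared across journals by Kruskal-Wallis;
    p-values are BH-adjusted over countries and countries with adjusted
    p < ``alpha`` are flagged as deviating from the pooled composition.
    """
    counts: dict[tuple[str, int, str], int] = {}
    journal_year_totals: dict[tuple[str, int], int] = {}
    for rec in rs:
        countries = _units_of_record(geos.get(rec.record_id, ()), "country")
        key_jy = (rec.journal, rec.year)
        journal_year_totals[key_jy] = journal_year_totals.get(key_jy, 0) + 1
        for c in countries:
            counts[(rec.journal, rec.year, c)] = counts.get((rec.journal, rec.year, c), 0) + 1

    journals = sorted({j for j, _ in journal_year_totals})
    if len(journals) < 2:
        raise ValueError("composition test needs at least 2 journals")
    country_totals: dict[str, int] = {}
    for (_, _, c), n in counts.items():
        country_totals[c] = country_totals.get(c, 0) + n
    countries = sorted(c for c, n in country_totals.items() if n >= min_articles)
    if len(countries) < 2:
        raise ValueError("composition test needs at least 2 countries above the threshold")
    years = sorted({y for _, y in journal_year_totals})

    prop = pd.DataFrame(0.0, index=journals, columns=countries)
    journal_totals = {j: sum(v for (jj, _), v in journal_year_totals.items() if jj == j) for j in journals}
    for (j, _, c), n in counts.items():
        if c in prop.columns:
            prop.loc[j, c] += n
    prop = prop.div(pd.Series(journal_totals), axis=0)

    rows = []
    for c in countries:
        by_journal = {
            j: [
                counts.get((j, y, c), 0) / journal_year_totals[(j, y)]
                for y in years
                if (j, y) in journal_year_totals
            ]
            for j in journals
        }
        res = group_compare(by_journal, test="kruskal_wallis")
        rows.append({"country": c, "statistic": res["statistic"][0], "pvalue": res["pvalue"][0]})
    tests = pd.DataFrame(rows)
    tests["pvalue_adj"] = bh_adjust(tests["pvalue"])
    tests["flagged"] = tests["pvalue_adj"] < alpha
    return prop, tests
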