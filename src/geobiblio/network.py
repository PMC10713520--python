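"""Citing-country x cited-country matrix, the Domestic Self-Citation Index,
and clustering of national citation fingerprints.

The DSCI of country alpha is the ratio of two proportions:

    eq1 = m[alpha, alpha] / sum_j m[alpha, j]
          (self-citation share of alpha's outgoing citations)
    eq2 = sum_{i != alpha} m[i, alpha] / sum_{i != alpha} sum_j m[i, j]
          (share of all other countries' outgoing citations received by alpha)

so DSCI = eq1 / eq2 equals exactly 1 under proportional mixing — when every
citing country allocates its citations in the same proportions, no country
prefers itself.  DSCI > 1 quantifies domestic preference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .metrics import spearman_corr

__all__ = [
    "CitationMatrix",
    "DSCIResult",
    "build_citation_matrix",
    "dsci",
    "dsci_table",
    "self_citation_summary",
    "cluster_citing_profiles",
    "dsci_correlations",
]


@dataclass
class CitationMatrix:
    """Square table of citation counts: rows cite, columns are cited."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.counts.columns):
            raise ValueError("row and column country order must agree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("citation counts must be non-negative")

    @property
    def countries(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total(self) -> float:
        return float(self.counts.to_numpy().sum())

    def __getitem__(self, key) -> float:
        i, j = key
        return float(self.counts.loc[i, j])


def build_citation_matrix(events: pd.DataFrame) -> CitationMatrix:
    """Aggregate (citing_country, cited_country, n) events to a dense matrix.

    Duplicate pairs are summed; unseen pairs over the country union are 0.
    """
    required = {"citing_country", "cited_country", "n"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    if (events["n"] < 0).any():
        raise ValueError("negative citation count in events table")
    countries = sorted(set(events["citing_country"]) | set(events["cited_country"]))
    m = (
        events.pivot_table(
            index="citing_country", columns="cited_country", values="n", aggfunc="sum", fill_value=0
        )
        .reindex(index=countries, columns=countries, fill_value=0)
        .astype(float)
    )
    m.index.name = "citing_country"
    m.columns.name = "cited_country"
    return CitationMatrix(m)


@dataclass(frozen=True)
class DSCIResult:
    country: str
    eq1: float  # self-citation share of outgoing citations
    eq2: float  # share of other countries' citations received
    dsci: float  # eq1/eq2; NaN when undefined
    defined: bool


def dsci(
    m: CitationMatrix,
    country: str,
    eq2_variant: str = "prose",
    include_diagonal: bool = True,
) -> DSCIResult:
    """Domestic Self-Citation Index of one country.

    ``eq2_variant="prose"`` (default): eq2 is the external citations
    received by the country divided by the total citations emitted by all
    other countries.  ``"literal"`` divides instead by the country's own
    citations to all other countries, an alternative reading kept for
    robustness comparisons.  ``include_diagonal=False`` removes other
    countries' self-citations from the prose denominator (sensitivity
    analysis).
    """
    if country not in m.countries:
        raise KeyError(f"country {country!r} not in matrix")
    a = m.counts.to_numpy(dtype=float)
    idx = m.countries.index(country)
    out_alpha = a[idx, :].sum()
    if out_alpha == 0:
        raise ValueError(f"country {country!r} has zero outgoing citations")
    eq1 = a[idx, idx] / out_alpha

    received_external = a[:, idx].sum() - a[idx, idx]
    if eq2_variant == "prose":
        others = np.ones(len(a), dtype=bool)
        others[idx] = False
        denom = a[others, :].sum()
        if not include_diagonal:
            denom -= np.diag(a)[others].sum()
    elif eq2_variant == "literal":
        denom = out_alpha - a[idx, idx]
    else:
        raise ValueError(f"unknown eq2 variant {eq2_variant!r}")
    eq2 = received_external / denom if denom > 0 else 0.0

    if eq2 > 0:
        return DSCIResult(country, float(eq1), float(eq2), float(eq1 / eq2), True)
    return DSCIResult(country, float(eq1), float(eq2), float("nan"), False)


def dsci_table(m: CitationMatrix, **kwargs) -> pd.DataFrame:
    """DSCI of every country with nonzero outgoing citations."""
    rows = []
    for c in m.countries:
        if m.counts.loc[c].sum() == 0:
            continue
        r = dsci(m, c, **kwargs)
        rows.append({"country": r.country, "eq1": r.eq1, "eq2": r.eq2, "dsci": r.dsci, "defined": r.defined})
    return pd.DataFrame(rows)


def self_citation_summary(m: CitationMatrix) -> dict:
    """Domestic share of all citations, per-country eq1, top citing country.

    Returns a dict with ``domestic_share`` (diagonal over total), ``eq1``
    (Series per citing country) and ``top_citing`` (for each cited country,
    the citing country contributing most of its received citations).
    """
    a = m.counts.to_numpy(dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValueError("empty citation matrix")
    row_sums = a.sum(axis=1)
    with np.errstate(invalid="ignore"):
        eq1 = np.where(row_sums > 0, np.diag(a) / row_sums, np.nan)
    top = {
        cited: m.counts[cited].idxmax()
        for cited in m.countries
        if m.counts[cited].sum() > 0
    }
    return {
        "domestic_share": float(np.trace(a) / total),
        "eq1": pd.Series(eq1, index=m.countries, name="eq1"),
        "top_citing": pd.Series(top, name="top_citing"),
    }


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id].replace(" ", "_")
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return walk(tree).rsplit(":", 1)[0] + ";"


def cluster_citing_profiles(
    m: CitationMatrix, n_clusters: int = 3, normalize: bool = True
) -> tuple[pd.Series, np.ndarray, str]:
    """Ward-linkage clustering of citing-country citation fingerprints.

    Each citing country's row is (by default) converted to proportions of
    its outgoing citations before computing Euclidean distances; Ward
    linkage on Euclidean distance corresponds to the Ward.D2 criterion.
    Returns (labels, linkage matrix, Newick dendrogram string).
    """
    n = len(m.countries)
    if n_clusters > n:
        raise ValueError(f"n_clusters {n_clusters} exceeds {n} citing countries")
    X = m.counts.to_numpy(dtype=float)
    if normalize:
        sums = X.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        X = X / sums
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return (
        pd.Series(labels, index=m.countries, name="cluster"),
        Z,
        _linkage_to_newick(Z, m.countries),
    )


def dsci_correlations(
    dsci_df: pd.DataFrame, rows: pd.DataFrame, excess: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlations of DSCI with size and excess metrics.

    Matches countries across the three tables and correlates DSCI against
    total citations, publication count, absolute excess and excess %.
    """
    d = dsci_df[dsci_df["defined"]].set_index("country")["dsci"]
    size = rows.set_index("unit")[["n_articles", "total_citations"]]
    exc = excess.set_index("unit")[["excess_articles", "excess_pct"]]
    joined = pd.concat([d, size, exc], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 countries shared across inputs")
    out = []
    for col, label in [
        ("total_citations", "citations"),
        ("n_articles", "publications"),
        ("excess_articles", "excess_count"),
        ("excess_pct", "excess_pct"),
    ]:
        try:
            rho, p = spearman_corr(joined["dsci"], joined[col])
        except ValueError:  # constant input
            rho, p = float("nan"), float("nan")
        out.append({"versus": label, "rho": rho, "pvalue": p, "n": len(joined)})
    return pd.DataFrame(out)
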