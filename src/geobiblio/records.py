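"""Reading and preprocessing of Web of Science style publication exports.

The export is a tab-delimited UTF-8 file with a header row of two-letter
field tags (``AU`` authors, ``SO`` journal, ``DT`` document type, ``PY``
publication year, ``C1``/``RP`` addresses, ``TC`` total citations, ``DI``
DOI, ``PG`` page count).  :class:`WosDialect` maps those tags onto record
fields so that other tabular dialects can be read with the same code path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "WosDialect",
    "DEFAULT_DIALECT",
    "PublicationRecord",
    "RecordSet",
    "parse_wos_export",
    "write_wos_export",
    "count_authors",
    "filter_records",
    "citations_per_year",
]

#: separator between multiple addresses inside one address field
ADDRESS_SEP = " | "


@dataclass(frozen=True)
class WosDialect:
    """Column mapping for a tab-delimited publication export."""

    authors: str = "AU"
    journal: str = "SO"
    doc_type: str = "DT"
    year: str = "PY"
    addresses: str = "C1"
    citations: str = "TC"
    doi: str = "DI"
    pages: str = "PG"
    record_id: str = "UT"

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.authors, self.journal, self.year, self.addresses, self.citations)


DEFAULT_DIALECT = WosDialect()


@dataclass(frozen=True)
class PublicationRecord:
    """One article as parsed from the export."""

    record_id: str
    journal: str
    doc_type: str
    year: int
    authors_raw: str
    author_count: int
    addresses: tuple[str, ...]
    total_citations: int
    doi: str | None = None
    page_length: int | None = None

    def __post_init__(self) -> None:
        if self.total_citations < 0:
            raise ValueError(f"total_citations < 0 for record {self.record_id!r}")
        if self.authors_raw and self.author_count < 1:
            raise ValueError(f"author_count < 1 for record {self.record_id!r}")


@dataclass
class RecordSet:
    """Ordered collection of :class:`PublicationRecord` with provenance."""

    records: list[PublicationRecord] = field(default_factory=list)
    provenance: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate record_id: {dup[dup > 1].index.tolist()}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PublicationRecord:
        return self.records[i]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per record; addresses joined with ``" | "``."""
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in self.records],
                "journal": [r.journal for r in self.records],
                "doc_type": [r.doc_type for r in self.records],
                "year": [r.year for r in self.records],
                "authors_raw": [r.authors_raw for r in self.records],
                "author_count": [r.author_count for r in self.records],
                "addresses": [ADDRESS_SEP.join(r.addresses) for r in self.records],
                "total_citations": [r.total_citations for r in self.records],
                "doi": [r.doi for r in self.records],
                "page_length": [r.page_length for r in self.records],
            }
        )

    def address_pairs(self) -> pd.DataFrame:
        """One row per (record, address) pair, in record order."""
        rows = [
            {"record_id": r.record_id, "address": a}
            for r in self.records
            for a in r.addresses
        ]
        return pd.DataFrame(rows, columns=["record_id", "address"])


def count_authors(authors_raw: str, literal: bool = False) -> int:
    """Number of authors in a semicolon-delimited author string.

    The default counts non-empty ``;``-separated tokens, which is robust to
    trailing delimiters in dirty exports.  ``literal=True`` applies the
    delimiter-count-plus-one rule instead.
    """
    if not authors_raw or not authors_raw.strip():
        raise ValueError("empty author field")
    if literal:
        return authors_raw.count(";") + 1
    return sum(1 for tok in authors_raw.split(";") if tok.strip())


def _parse_int(value, default=None):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return default
    try:
        return int(float(value))
    except (TypeError, ValueError):
        return default


def parse_wos_export(
    path: str | Path | io.StringIO, dialect: WosDialect = DEFAULT_DIALECT
) -> RecordSet:
    """Parse a tab-delimited publication export into a :class:`RecordSet`.

    Rows missing the year or the journal are dropped; the count of dropped
    rows is recorded on the returned set.  A header missing a mandatory
    column is a fatal error naming that column.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise ValueError(f"unreadable export file {path!r}: {exc}") from exc

    for col in dialect.mandatory:
        if col not in df.columns:
            raise ValueError(f"export header is missing mandatory field {col!r}")

    records: list[PublicationRecord] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        year = _parse_int(row.get(dialect.year))
        journal = (row.get(dialect.journal) or "").strip()
        if year is None or not journal:
            dropped += 1
            continue
        authors = (row.get(dialect.authors) or "").strip()
        rid = (row.get(dialect.record_id) or "").strip() or f"R{i:06d}"
        addr_field = (row.get(dialect.addresses) or "").strip()
        addresses = tuple(a.strip() for a in addr_field.split(ADDRESS_SEP.strip()) if a.strip())
        records.append(
            PublicationRecord(
                record_id=rid,
                journal=journal,
                doc_type=(row.get(dialect.doc_type) or "").strip() or "Article",
                year=year,
                authors_raw=authors,
                author_count=count_authors(authors) if authors else 0,
                addresses=addresses,
                total_citations=_parse_int(row.get(dialect.citations), default=0) or 0,
                doi=(row.get(dialect.doi) or "").strip() or None,
                page_length=_parse_int(row.get(dialect.pages)),
            )
        )
    return RecordSet(records, provenance=f"parsed from {path}", n_dropped=dropped)


def write_wos_export(
    rs: RecordSet, path: str | Path, dialect: WosDialect = DEFAULT_DIALECT
) -> None:
    """Write a :class:`RecordSet` back to the tab-delimited export dialect."""
    df = pd.DataFrame(
        {
            dialect.record_id: [r.record_id for r in rs],
            dialect.authors: [r.authors_raw for r in rs],
            dialect.journal: [r.journal for r in rs],
            dialect.doc_type: [r.doc_type for r in rs],
            dialect.year: [r.year for r in rs],
            dialect.addresses: [ADDRESS_SEP.join(r.addresses) for r in rs],
            dialect.citations: [r.total_citations for r in rs],
            dialect.doi: [r.doi or "" for r in rs],
            dialect.pages: ["" if r.page_length is None else r.page_length for r in rs],
        }
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def filter_records(
    rs: RecordSet,
    journals: Iterable[str],
    year_min: int,
    year_max: int,
    doc_types: Iterable[str] = ("Article",),
) -> RecordSet:
    """Retain records matching journal, document type and year window."""
    journals = set(journals)
    doc_types = set(doc_types)
    if not journals:
        raise ValueError("empty journal set: pass the journals to retain explicitly")
    if year_min > year_max:
        raise ValueError(f"year_min {year_min} > year_max {year_max}")
    kept = [
        r
        for r in rs
        if r.journal in journals and r.doc_type in doc_types and year_min <= r.year <= year_max
    ]
    prov = (
        f"{rs.provenance}; filtered journals={sorted(journals)} "
        f"years={year_min}-{year_max} doc_types={sorted(doc_types)}"
    )
    return RecordSet(kept, provenance=prov, n_dropped=rs.n_dropped + (len(rs) - len(kept)))


def citations_per_year(total_citations: int, year: int, reference_year: int) -> float:
    """Average citations per year since publication.

    The denominator is ``reference_year - year`` floored at 1, so articles
    published in the reference year count their citations over one year.
    """
    if reference_year < year:
        raise ValueError(f"reference_year {reference_year} precedes publication year {year}")
    if total_citations < 0:
        raise ValueError("total_citations < 0")
    return total_citations / max(1, reference_year - year)
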