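import numpy as np
import pandas as pd
import pytest

from geobiblio import (
    RecordSet,
    SyntheticConfig,
    default_gazetteer,
    generate_citations,
    generate_publications,
)


@pytest.fixture(scope="session")
def gazetteer():
    return default_gazetteer()


@pytest.fixture(scope="session")
def small_cfg():
    """Small synthetic corpus configuration shared across tests."""
    return SyntheticConfig(n_articles=800, seed=42)


@pytest.fixture(scope="session")
def small_corpus(small_cfg, gazetteer):
    """(records-with-citations, citing events, publication truth, citation truth)."""
    rs, truth = generate_publications(small_cfg, gazetteer)
    rs, events, cite_truth = generate_citations(rs, small_cfg)
    return rs, events, truth, cite_truth


@pytest.fixture(scope="session")
def big_cfg():
    """Study-scale corpus: 10k articles, home-journal affinity, one injected trend."""
    return SyntheticConfig(n_articles=10_000, trend_slopes={"Canada": -3.0}, seed=20240501)


@pytest.fixture(scope="session")
def big_corpus(big_cfg, gazetteer):
    rs, truth = generate_publications(big_cfg, gazetteer)
    rs, events, cite_truth = generate_citations(rs, big_cfg)
    return rs, events, truth, cite_truth


def make_records(rows) -> RecordSet:
    """Build a RecordSet from (journal, year, citations, addresses) tuples."""
    from geobiblio import PublicationRecord

    recs = []
    for i, (journal, year, citations, addresses) in enumerate(rows):
        recs.append(
            PublicationRecord(
                record_id=f"T{i:04d}",
                journal=journal,
                doc_type="Article",
                year=year,
                authors_raw="Smith J; Doe A",
                author_count=2,
                addresses=tuple(addresses),
                total_citations=citations,
            )
        )
    return RecordSet(recs, provenance="test fixture")
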