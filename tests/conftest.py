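import pytest

from ribopool.catalog import load_diagnostic_matrix, load_published_tables
from ribopool.reference import ReferenceFrame, materialize_ribotype_sequence


@pytest.fixture(scope="session")
def frame():
    return ReferenceFrame()


@pytest.fixture(scope="session")
def matrix():
    return load_diagnostic_matrix()


@pytest.fixture(scope="session")
def catalog_sequences(frame, matrix):
    """Materialized ungapped sequence of every catalog ribotype."""
    return {
        name: materialize_ribotype_sequence(frame, definition)
        for name, definition in matrix.rows.items()
    }


@pytest.fixture(scope="session")
def published_tables():
    """Packaged transcription of the study's per-accession major-ribotype
    tables (printed counts and percents, inconsistencies preserved)."""
    return load_published_tables()
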