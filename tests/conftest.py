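import pytest
from rdkit import RDLogger

from ista.engine import QueryCompound
from ista.fixtures import FixtureSpec, generate_fixture_set
from ista.templates import build_template_db

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def fixture_set():
    """Two reactions and one query per archetype, fixed seed."""
    return generate_fixture_set(
        FixtureSpec(seed=7, n_per_archetype=2, n_queries_per_archetype=1)
    )


@pytest.fixture(scope="session")
def template_db(fixture_set):
    templates, substructures, report = build_template_db(fixture_set.reactions)
    return templates, substructures, report


@pytest.fixture(scope="session")
def fixture_queries(fixture_set):
    return [
        QueryCompound(row.QUERY_ID, row.SMILES)
        for row in fixture_set.queries.itertuples()
    ]
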