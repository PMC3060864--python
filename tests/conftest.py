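"""Shared fixtures for the test suite."""

from __future__ import annotations

import pytest

from semkb.fixtures import (  # noqa: F401  (re-exported for test modules)
    FixtureSpec,
    build_model,
    generate_kb,
    random_dag_terms,
    random_query,
    random_query_mapping,
)
from semkb.schema import DataModel


@pytest.fixture(scope="session")
def model() -> DataModel:
    return build_model()


@pytest.fixture()
def small_kb():
    kb, truth = generate_kb(FixtureSpec(seed=7, n_patients=25, n_genes=10,
                                        n_proteins=10, n_compounds=5,
                                        n_pathways=3, ontology_size=20))
    return kb, truth


def small_spec(seed: int) -> FixtureSpec:
    """A spec producing a KB of <= ~200 objects for property tests."""
    return FixtureSpec(
        seed=seed, n_patients=15, n_genes=8, n_proteins=8, n_compounds=4,
        n_pathways=3, ontology_size=14,
    )
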