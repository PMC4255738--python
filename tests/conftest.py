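"""Shared fixtures: one synthetic planted-topic corpus per session, with
its index, vector databases and planted gold benchmark."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from corpusrel.index import build_index
from corpusrel.synthetic import SyntheticSpec, generate_corpus, generate_gold
from corpusrel.vectorizer import BuildConfig, build_vector_db

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_spec():
    return SyntheticSpec()  # canonical self-test conditions (seed 7)


@pytest.fixture(scope="session")
def fixture_docs(fixture_spec):
    return generate_corpus(fixture_spec)


@pytest.fixture(scope="session")
def fixture_index(fixture_docs):
    return build_index(fixture_docs)


@pytest.fixture(scope="session")
def fixture_gold(fixture_spec):
    return generate_gold(fixture_spec, n_pos=25, n_neg=25)


@pytest.fixture(scope="session")
def dbs_by_c(fixture_docs):
    """Plain-variant vector DBs across the trimming grid."""
    return {
        c: build_vector_db(fixture_docs, BuildConfig(variant="plain", c=c))
        for c in (0.05, 0.1, 0.2, 0.4)
    }


@pytest.fixture(scope="session")
def db_plain(dbs_by_c):
    return dbs_by_c[0.2]


@pytest.fixture(scope="session")
def db_tgsp(fixture_docs):
    return build_vector_db(fixture_docs, BuildConfig(variant="tgsp", c=0.5))
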