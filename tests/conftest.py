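"""Shared fixtures: one generated ontology/corpus and one trained recognizer."""

import pytest

from ontoqa import association as am
from ontoqa import fixtures as fx
from ontoqa import ontology as om
from ontoqa import recognition as rec
from ontoqa import sparql as sp
from ontoqa.pipeline import Pipeline


@pytest.fixture(scope="session")
def spec():
    return fx.FixtureSpec()


@pytest.fixture(scope="session")
def fixture(spec):
    return fx.generate_ontology(spec)


@pytest.fixture(scope="session")
def model(fixture, spec):
    return om.load_ontology(fixture.ontology, list(spec.labels))


@pytest.fixture(scope="session")
def graph(model, fixture):
    return om.build_property_graph(model, fixture.data)


@pytest.fixture(scope="session")
def dag(graph, model):
    return om.to_dag(graph, roots=[model.root])


@pytest.fixture(scope="session")
def lca_table(dag):
    return am.build_lca_table(dag)


@pytest.fixture(scope="session")
def corpus_and_questions(spec, fixture):
    return fx.generate_corpus(spec, fixture)


@pytest.fixture(scope="session")
def corpus(corpus_and_questions):
    return corpus_and_questions[0]


@pytest.fixture(scope="session")
def questions(corpus_and_questions):
    return corpus_and_questions[1]


@pytest.fixture(scope="session")
def endpoint(fixture):
    return sp.LocalEndpoint(fixture.data)


@pytest.fixture(scope="session")
def trained_crf(corpus, model):
    # 160/40 train/held-out split of the 200-question corpus
    return rec.train(rec.TrainingCorpus(corpus.items[:160]), seed=7, model=model)


@pytest.fixture(scope="session")
def pipeline(model, graph, dag, lca_table, trained_crf, endpoint, fixture):
    return Pipeline(model, graph, dag, lca_table, trained_crf, endpoint, fixture.data)
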