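import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bioevex as bx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


FIG_TEXT = "Importantly the over-expression of lamin promote tumorigenesis in samples."
FIG_A1 = "T1\tGene 35 40\tlamin\nT2\tCancer 49 62\ttumorigenesis\n"
FIG_A2 = (
    "T3\tExpression 16 31\tover-expression\n"
    "T4\tRegulation 41 48\tpromote\n"
    "E1\tExpression:T3 Theme:T1\n"
    "E2\tRegulation:T4 Theme:T2 Cause:E1\n"
    "M1\tNegation E2\n"
)


@pytest.fixture(scope="session")
def toy_schema():
    return bx.default_toy_schema()


@pytest.fixture()
def nested_doc(toy_schema):
    """A sentence with a flat event nested as the Cause of a regulation."""
    return bx.read_standoff_document(FIG_TEXT, FIG_A1, FIG_A2, schema=toy_schema)


@pytest.fixture(scope="session")
def tiny_corpus(toy_schema):
    return bx.generate_documents(toy_schema, bx.SyntheticConfig(seed=5), 6)


@pytest.fixture(scope="session")
def tiny_model(toy_schema, tiny_corpus):
    """A briefly trained single model for cheap behavioural tests."""
    cfg = bx.TrainConfig(epochs=8, ensemble_size=1, seed=3)
    models, _ = bx.train(tiny_corpus, toy_schema, cfg)
    return models, cfg


@pytest.fixture(scope="session")
def trained_setup(toy_schema):
    """The overfit study setup: 20 training documents, 200 epochs, hd=32.

    Shared (session-scoped) because training dominates suite runtime; the
    held-out split comes from the same generator with a different seed.
    """
    train_docs = bx.generate_documents(toy_schema, bx.SyntheticConfig(seed=11), 20,
                                       doc_prefix="train")
    held_docs = bx.generate_documents(toy_schema, bx.SyntheticConfig(seed=12), 10,
                                      doc_prefix="held")
    cfg = bx.TrainConfig(epochs=200, ensemble_size=1, seed=0)
    models, histories = bx.train(train_docs, toy_schema, cfg)
    return {
        "schema": toy_schema,
        "train_docs": train_docs,
        "held_docs": held_docs,
        "cfg": cfg,
        "models": models,
        "history": histories[0],
    }
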