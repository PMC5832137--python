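import numpy as np
import pytest

from emrdx.records import EMRecord
from emrdx.synthetic import SyntheticConfig, generate_corpus


def make_record(rid="r1", chief=(), phys=(), obst=(), aux=(), labels=("dx",), t=None):
    return EMRecord(
        record_id=rid,
        sections={
            "chief_complaints": list(chief),
            "physical_exam": list(phys),
            "obstetric_exam": list(obst),
            "auxiliary_exam": list(aux),
        },
        raw_labels=set(labels),
        record_time=t,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """300 records, 12 labels, 3 true topics — quick but learnable."""
    config = SyntheticConfig(
        n_records=300, n_labels=12, n_topics_true=3, vocab_size=200, seed=42
    )
    corpus, truth = generate_corpus(config)
    return config, corpus, truth


@pytest.fixture(scope="session")
def tiny_docs():
    """Two-cluster toy corpus for embedding tests."""
    rng = np.random.default_rng(5)
    docs = []
    for _ in range(40):
        docs.append(list(rng.permutation(["a", "b", "c"] * 3)))
        docs.append(list(rng.permutation(["x", "y", "z"] * 3)))
    return docs
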