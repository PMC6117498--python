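import numpy as np
import pytest

import reviewminer as rm


@pytest.fixture(scope="session")
def taxonomy():
    return rm.load_taxonomy()


@pytest.fixture(scope="session")
def small_labeled_corpus():
    """A small two-group corpus with a planted symptom-topic shift."""
    config = rm.GeneratorConfig(
        L=9, vocab_size=120,
        group_sizes={"acute": 120, "chronic": 120},
        label_prevalence={
            "acute": [0.3, 0.3, 0.3, 0.25, 0.2, 0.3, 0.35, 0.9, 0.25],
            "chronic": [0.3, 0.3, 0.3, 0.45, 0.5, 0.3, 0.25, 0.1, 0.45],
        },
        group_metadata={
            "acute": {"disease": "influenza"},
            "chronic": {"disease": "diabetes"},
        },
        default_doc_length=(60.0, 10.0),
        seed=11,
    )
    return rm.generate_corpus(config)


def make_reviews(n, with_labels=False):
    reviews = []
    for i in range(n):
        reviews.append(rm.Review(
            doc_id=f"r{i}",
            tokens=[f"tok{i}", "shared", f"tok{i}"],
            labels={"ME"} if with_labels else None,
            disease="influenza" if i % 2 else "diabetes",
            hospital_level="A" if i % 3 else "B",
            doctor_id=f"dr{i % 2}",
        ))
    return rm.Corpus(reviews)
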