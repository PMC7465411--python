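import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from notestruct import (  # noqa: E402
    ClassifierConfig,
    GeneratorConfig,
    generate_corpus,
    generate_taxonomy,
    generate_unstructured_notes,
    heading_vectors,
    split_corpus,
    train_classifier,
)


@pytest.fixture(scope="session")
def separable():
    """The separable recovery setting: 20 leaf headings, ~200 sentences per
    heading, near-disjoint topics, bow_softmax classifier."""
    cfg = GeneratorConfig(seed=1)
    tax = generate_taxonomy(cfg)
    corpus = generate_corpus(tax, cfg)
    train, dev, test = split_corpus(corpus, (0.6, 0.2, 0.2), seed=1)
    model = train_classifier(
        train, dev, ClassifierConfig(backend="bow_softmax", max_epochs=100, patience=10, seed=1)
    )
    return {
        "config": cfg,
        "taxonomy": tax,
        "corpus": corpus,
        "train": train,
        "dev": dev,
        "test": test,
        "model": model,
        "vectors": heading_vectors(model),
    }


@pytest.fixture(scope="session")
def conflated():
    """Same setting with three planted cross-category conflated pairs."""
    cfg = GeneratorConfig(seed=1, n_conflated_pairs=3)
    tax = generate_taxonomy(cfg)
    corpus = generate_corpus(tax, cfg)
    train, dev, test = split_corpus(corpus, (0.6, 0.2, 0.2), seed=1)
    model = train_classifier(
        train, dev, ClassifierConfig(backend="bow_softmax", max_epochs=100, patience=10, seed=1)
    )
    return {
        "config": cfg,
        "taxonomy": tax,
        "corpus": corpus,
        "test": test,
        "model": model,
        "vectors": heading_vectors(model),
    }


@pytest.fixture(scope="session")
def free_notes(separable):
    """Forty free-narrative notes with gold structure from the separable
    setting."""
    return generate_unstructured_notes(separable["taxonomy"], separable["config"], n_notes=40)
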