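import numpy as np
import pytest
from hypothesis import settings

from neurotext.linking import Linker
from neurotext.synthetic import SynthConfig, generate_corpus, generate_ontology
from neurotext.types import OntologyEntry

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


def random_bio(rng: np.random.Generator, n: int) -> list[str]:
    """Uniformly sampled BIO-valid label sequence of length n."""
    labels = []
    prev = "O"
    for _ in range(n):
        if prev == "O":
            lab = rng.choice(["O", "B-BrainRegion"], p=[0.6, 0.4])
        else:
            lab = rng.choice(["O", "B-BrainRegion", "I-BrainRegion"], p=[0.4, 0.2, 0.4])
        labels.append(str(lab))
        prev = labels[-1]
    return labels


@pytest.fixture(scope="session")
def synth_corpus():
    """Small default-condition synthetic corpus with ground truth."""
    return generate_corpus(SynthConfig(n_documents=40, sentences_per_document=6, seed=3))


@pytest.fixture(scope="session")
def synth_ontology():
    entries, gazetteer = generate_ontology(SynthConfig(n_regions=30, seed=5))
    return entries, gazetteer


@pytest.fixture(scope="session")
def toy_entries():
    """Hand-written mini dictionary used by the linking tests."""
    return [
        OntologyEntry("A:01", "ventral tegmental area", frozenset({"VTA"})),
        OntologyEntry("A:02", "lateral habenula", frozenset({"LH"})),
        OntologyEntry("A:03", "hippocampus"),
        OntologyEntry("A:04", "CA1"),
        OntologyEntry("A:05", "paraventricular nucleus of the thalamus",
                      frozenset({"PVT"})),
        OntologyEntry("A:06", "paraventricular hypothalamic nucleus",
                      frozenset({"PVH"})),
        OntologyEntry("A:07", "geniculate nucleus"),
    ]


@pytest.fixture(scope="session")
def toy_linker(toy_entries):
    return Linker(toy_entries)
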