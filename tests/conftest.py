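import pytest

from phenoprompt.corpus import AnnotationSet, Document, EntityMention
from phenoprompt.synthetic import GeneratorConfig, generate_corpus

FIG_TEXT = "Keratomalacia is a cause of corneal scarring."
FIG_ANN = "T1\tRAREDISEASE 0 13\tKeratomalacia\nT2\tSIGN 28 44\tcorneal scarring\n"


@pytest.fixture
def fig_doc():
    return Document(doc_id="fig1", text=FIG_TEXT)


@pytest.fixture
def fig_gold(fig_doc):
    return AnnotationSet(
        doc_id="fig1",
        role="gold",
        mentions=[
            EntityMention(((0, 13),), "rare_disease", "Keratomalacia"),
            EntityMention(((28, 44),), "sign", "corneal scarring"),
        ],
    )


@pytest.fixture(scope="session")
def corpus_200():
    """The standard 200-document fixture corpus (seeded, deterministic)."""
    return generate_corpus(GeneratorConfig(n_docs=200, seed=7))


@pytest.fixture(scope="session")
def corpus_30():
    return generate_corpus(GeneratorConfig(n_docs=30, seed=3))
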