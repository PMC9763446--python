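import pytest

from causaltext.corpus import Corpus, Instance
from causaltext.ner import EntityLexicon
from causaltext.synthetic import GeneratorConfig, generate_corpus


def make_corpus(texts_labels, prefix="i"):
    return Corpus(
        tuple(
            Instance.from_text(f"{prefix}{k}", text, label)
            for k, (text, label) in enumerate(texts_labels)
        )
    )


@pytest.fixture(scope="session")
def toy_separable_corpus():
    """Positives all contain 'hepatotoxic'; linearly separable."""
    rows = []
    for k in range(12):
        rows.append((f"the hepatotoxic drug number {k} damaged the liver", "positive"))
        rows.append((f"the benign compound number {k} was well tolerated", "negative"))
    return make_corpus(rows)


@pytest.fixture(scope="session")
def default_synthetic():
    """Default strong-effect generator output: (corpus, lexicon, truth)."""
    return generate_corpus(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_synthetic():
    """Smaller corpus (faster fits) with the same planted structure."""
    return generate_corpus(
        GeneratorConfig(
            n_sentences=1500,
            filler_vocab_size=600,
            n_drug=4,
            n_gene=3,
            n_disease=13,
            n_causal=4,
            seed=0,
        )
    )


@pytest.fixture()
def tiny_lexicon():
    lexicon = EntityLexicon()
    lexicon.add("liver failure", "liver failure", "disease")
    lexicon.add("acute liver failure", "acute liver failure", "disease")
    lexicon.add("jaundice", "jaundice", "disease")
    return lexicon
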