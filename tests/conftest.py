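import pytest

from cryogap.corpus_io import ArticleRecord, TaxonBackbone, read_lexicon
from cryogap.synthetic_data import (
    CorpusConfig,
    default_lexicon_for,
    generate_backbone,
    generate_corpus,
)


def article(article_id: str, title: str, abstract: str = "") -> ArticleRecord:
    return ArticleRecord(article_id, title, abstract)


@pytest.fixture
def backbone() -> TaxonBackbone:
    """Tiny hand-built backbone with a homograph genus and one alias."""
    return TaxonBackbone(
        genera=frozenset({"Malus", "Pyrus", "Medium", "Shorea"}),
        families=frozenset({"Rosaceae", "Dipterocarpaceae", "Orchidaceae"}),
        genus_to_family={
            "Malus": "Rosaceae",
            "Pyrus": "Rosaceae",
            "Medium": "Rosaceae",
            "Shorea": "Dipterocarpaceae",
        },
        excluded_names=frozenset({"Medium"}),
        common_names={"apple": ("Malus", "Rosaceae")},
    )


@pytest.fixture(scope="session")
def default_lexicon():
    return read_lexicon(None)


@pytest.fixture(scope="session")
def synth_backbone():
    return generate_backbone(20, 5, seed=11)


@pytest.fixture(scope="session")
def synth_lexicon(synth_backbone):
    return default_lexicon_for(synth_backbone)


@pytest.fixture(scope="session")
def synth_corpus(synth_backbone):
    """800-article synthetic corpus with sidecar truth (fixed seed)."""
    return generate_corpus(synth_backbone, 800, CorpusConfig(), seed=23)
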