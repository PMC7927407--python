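import numpy as np
import pytest

from cobm25.corpus_io import Document, build_index
from cobm25.expansion import ExpandedQuery


def make_random_documents(rng: np.random.Generator, n_docs: int,
                          vocab_size: int = 25) -> list[Document]:
    """Small random corpus with single- and multi-word word-list terms."""
    vocab = [f"t{i}" for i in range(vocab_size)]
    docs = []
    for i in range(n_docs):
        abstract = " ".join(rng.choice(vocab, size=rng.integers(0, 30)))
        def terms(max_terms):
            out = []
            for _ in range(rng.integers(0, max_terms)):
                k = int(rng.integers(1, 4))
                out.append(" ".join(rng.choice(vocab, size=k)))
            return out
        docs.append(Document.from_fields(
            f"D{i:04d}", abstract,
            chemical_terms=terms(3), mesh_terms=terms(5), keyword_terms=terms(3),
            stopwords=(),
        ))
    return docs


def make_random_query(rng: np.random.Generator, vocab_size: int = 25) -> ExpandedQuery:
    vocab = [f"t{i}" for i in range(vocab_size)]
    def pick(n):
        return [str(t) for t in rng.choice(vocab, size=n, replace=False)]
    wordlist = [tuple(pick(int(rng.integers(1, 3)))) for _ in range(rng.integers(1, 5))]
    return ExpandedQuery(
        topic_id="1",
        abstract_terms=tuple(pick(int(rng.integers(1, 5)))),
        wordlist_terms=tuple(dict.fromkeys(wordlist)),
        disease_terms=(tuple(pick(1)),),
        gene_terms=tuple((t,) for t in pick(int(rng.integers(1, 3)))),
    )


@pytest.fixture
def tiny_docs() -> list[Document]:
    """Four handcrafted articles exercising every field combination."""
    return [
        Document.from_fields(
            "PMID1",
            "liposarcoma cdk4 amplification liposarcoma response",
            chemical_terms=["cyclin dependent kinase 4"],
            mesh_terms=["Liposarcoma", "Middle Aged", "Human"],
            keyword_terms=["cdk4"],
            stopwords=(),
        ),
        Document.from_fields(
            "PMID2",
            "melanoma braf v600e treatment outcome",
            mesh_terms=["Melanoma", "Human"],
            stopwords=(),
        ),
        Document.from_fields(
            "PMID3",
            "cdk4 inhibitor trial results",
            stopwords=(),
        ),
        Document.from_fields("PMID4", "", keyword_terms=["braf"], stopwords=()),
    ]


@pytest.fixture
def tiny_index(tiny_docs):
    return build_index(tiny_docs)
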