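"""Synthetic MEDLINE-style test collections with planted co-word structure.

The generator emulates the statistical shape of a precision-medicine
abstract corpus: Zipf-distributed vocabulary, Poisson field lengths whose
defaults match the published corpus statistics (mean abstract length 77.5
tokens after stop-word removal; chemical / MeSH / keyword term-list means
3.8 / 10.5 / 4.1, carried by roughly 49% / 92% / 15% of articles), and a
set of disease–gene topic pairs planted into a controllable fraction of
documents. Relevance judgments are drawn from a simple generative model in
which the probability of relevance jumps by ``coword_boost`` when a
document carries both the topic's disease and gene, which is exactly the
association the co-word score is designed to exploit.

Planted pairs are placed either inside one field or across two different
fields (``within_field_fraction``), so the "cross" and "within" co-word
detection modes are distinguishable on generated data. Everything is
driven by a single :class:`numpy.random.Generator`; a fixed seed gives
byte-identical XML.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lxml import etree

from .corpus_io import CorpusError, Qrels, Topic, parse_medline_xml

_FIELDS = ("abstract", "chemical", "mesh", "keyword")

_LIFE_STAGES = ("Infant", "Child", "Adolescent", "Young", "Middle Aged",
                "Aged", "Adult")


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the corpus-scale statistics."""

    n_docs: int = 1000
    vocab_size: int = 2000
    zipf_exponent: float = 1.1
    mean_abstract_len: float = 77.5
    mean_chemical_len: float = 3.8
    mean_mesh_len: float = 10.5
    mean_keyword_len: float = 4.1
    frac_chemical: float = 0.49
    frac_mesh: float = 0.92
    frac_keyword: float = 0.15
    n_topics: int = 10
    coword_fraction: float = 0.15    # docs carrying a planted disease+gene pair
    single_term_fraction: float = 0.10  # docs carrying only one half of a pair
    within_field_fraction: float = 0.5
    base_relevance: float = 0.01
    coword_boost: float = 0.7
    grade2_fraction: float = 0.3

    def __post_init__(self):
        if self.vocab_size <= 0:
            raise CorpusError("zero vocabulary")
        if self.n_docs <= 0 or self.n_topics <= 0:
            raise CorpusError("n_docs and n_topics must be positive")
        for p in (self.frac_chemical, self.frac_mesh, self.frac_keyword,
                  self.coword_fraction, self.single_term_fraction,
                  self.within_field_fraction, self.base_relevance,
                  self.coword_boost, self.grade2_fraction):
            if not (0.0 <= p <= 1.0):
                raise CorpusError("probabilities must lie in [0, 1]")


@dataclass
class SynthDoc:
    """A generated article before XML serialization."""

    doc_id: str
    abstract_words: list[str]
    chemical_terms: list[str]
    mesh_terms: list[str]
    keyword_terms: list[str]
    planted: dict[int, tuple[str, ...]]  # topic -> fields carrying its terms

    def contains_pair(self, topic: int) -> bool:
        fields = self.planted.get(topic, ())
        return any(f.startswith("d:") for f in fields) and any(
            f.startswith("g:") for f in fields
        )


def _zipf_probs(vocab_size: int, s: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks ** (-s)
    return p / p.sum()


def disease_token(topic: int) -> str:
    return f"dis{topic:03d}"


def gene_token(topic: int) -> str:
    return f"gen{topic:03d}"


def generate_documents(config: SynthConfig, rng: np.random.Generator) -> list[SynthDoc]:
    """Draw the document set, planting disease/gene terms per topic."""
    probs = _zipf_probs(config.vocab_size, config.zipf_exponent)
    vocab = np.array([f"w{i:05d}" for i in range(config.vocab_size)])

    def draw_words(n: int) -> list[str]:
        return list(vocab[rng.choice(config.vocab_size, size=n, p=probs)])

    def draw_terms(mean_len: float) -> list[str]:
        n_terms = 1 + rng.poisson(max(mean_len - 1.0, 0.0))
        terms = []
        for _ in range(n_terms):
            n_tok = 2 if rng.random() < 0.2 else 1
            terms.append(" ".join(draw_words(n_tok)))
        return terms

    docs: list[SynthDoc] = []
    for i in range(config.n_docs):
        abstract = draw_words(rng.poisson(config.mean_abstract_len))
        chem = draw_terms(config.mean_chemical_len) if rng.random() < config.frac_chemical else []
        # demographic check-tags (Human, sex, life stage) are part of the
        # MeSH budget: 1.0 expected decorations, so the total mean matches.
        # Tag prevalence stays below half the word-list documents so the
        # expanded-word IDFs keep their usual positive sign.
        mesh = (draw_terms(config.mean_mesh_len - 1.0)
                if rng.random() < config.frac_mesh else [])
        kw = draw_terms(config.mean_keyword_len) if rng.random() < config.frac_keyword else []
        if mesh:
            if rng.random() < 0.4:
                mesh.append("Human")
            if rng.random() < 0.3:
                mesh.append("Male" if rng.random() < 0.5 else "Female")
            if rng.random() < 0.3:
                mesh.append(_LIFE_STAGES[int(rng.integers(len(_LIFE_STAGES)))])
        doc = SynthDoc(f"SYN{i:07d}", abstract, chem, mesh, kw, {})

        u = rng.random()
        if u < config.coword_fraction:
            topic = int(rng.integers(config.n_topics))
            _plant_pair(doc, topic, config, rng)
        elif u < config.coword_fraction + config.single_term_fraction:
            topic = int(rng.integers(config.n_topics))
            which = "d" if rng.random() < 0.5 else "g"
            _plant_term(doc, topic, which, _pick_field(rng), rng)
        docs.append(doc)
    return docs


def _pick_field(rng: np.random.Generator) -> str:
    # abstracts and MeSH are the most common carriers
    return _FIELDS[int(rng.choice(4, p=[0.45, 0.1, 0.35, 0.1]))]


def _plant_pair(doc: SynthDoc, topic: int, config: SynthConfig,
                rng: np.random.Generator) -> None:
    f1 = _pick_field(rng)
    if rng.random() < config.within_field_fraction:
        f2 = f1
    else:
        others = [f for f in _FIELDS if f != f1]
        f2 = others[int(rng.integers(3))]
    _plant_term(doc, topic, "d", f1, rng)
    _plant_term(doc, topic, "g", f2, rng)


def _plant_term(doc: SynthDoc, topic: int, which: str, field: str,
                rng: np.random.Generator) -> None:
    token = disease_token(topic) if which == "d" else gene_token(topic)
    if field == "abstract":
        pos = int(rng.integers(len(doc.abstract_words) + 1))
        doc.abstract_words.insert(pos, token)
    elif field == "chemical":
        doc.chemical_terms.append(token)
    elif field == "mesh":
        doc.mesh_terms.append(token)
    else:
        doc.keyword_terms.append(token)
    doc.planted.setdefault(topic, ())
    doc.planted[topic] = doc.planted[topic] + (f"{which}:{field}",)


def corpus_to_xml(docs: Sequence[SynthDoc]) -> bytes:
    """Serialize to the MEDLINE dialect accepted by ``parse_medline_xml``."""
    root = etree.Element("PubmedArticleSet")
    for doc in docs:
        cit = etree.SubElement(root, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = doc.doc_id
        art = etree.SubElement(cit, "Article")
        abstract = etree.SubElement(art, "Abstract")
        etree.SubElement(abstract, "AbstractText").text = " ".join(doc.abstract_words)
        if doc.chemical_terms:
            cl = etree.SubElement(cit, "ChemicalList")
            for t in doc.chemical_terms:
                chem = etree.SubElement(cl, "Chemical")
                etree.SubElement(chem, "NameOfSubstance").text = t
        if doc.mesh_terms:
            ml = etree.SubElement(cit, "MeshHeadingList")
            for t in doc.mesh_terms:
                mh = etree.SubElement(ml, "MeshHeading")
                etree.SubElement(mh, "DescriptorName").text = t
        if doc.keyword_terms:
            kl = etree.SubElement(cit, "KeywordList")
            for t in doc.keyword_terms:
                etree.SubElement(kl, "Keyword").text = t
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def generate_corpus(config: SynthConfig, rng: np.random.Generator) -> bytes:
    """Generate a corpus and return its XML serialization."""
    return corpus_to_xml(generate_documents(config, rng))


_AGE_CHOICES = (8, 16, 24, 38, 45, 52, 64, 71, 83)


def generate_topics_and_qrels(
    config: SynthConfig, docs: Sequence[SynthDoc], rng: np.random.Generator,
) -> tuple[list[Topic], Qrels, dict[str, set[str]]]:
    """Topics over the planted pairs plus sampled graded judgments.

    Returns (topics, qrels, coword_docs) where ``coword_docs`` is the
    ground-truth topic -> co-word-document mapping. The relevance model is
    P(relevant) = base_relevance + coword_boost * 1[pair present]; relevant
    documents get grade 2 with probability ``grade2_fraction``, else 1.
    """
    planted_topics = {t for d in docs for t in d.planted
                      if d.contains_pair(t)}
    if config.n_topics > len(planted_topics) and config.coword_fraction > 0:
        missing = set(range(config.n_topics)) - planted_topics
        if missing:
            raise CorpusError(
                f"more topics than planted disease/gene pairs (no documents for {sorted(missing)})"
            )
    topics: list[Topic] = []
    qrels = Qrels()
    coword_docs: dict[str, set[str]] = {}
    for t in range(config.n_topics):
        tid = str(t + 1)
        age = int(_AGE_CHOICES[rng.integers(len(_AGE_CHOICES))])
        sex = "male" if rng.random() < 0.5 else "female"
        topics.append(Topic(
            topic_id=tid,
            disease=disease_token(t),
            gene_field=gene_token(t).upper(),
            demographic=f"{age}-year-old {sex}",
        ))
        cw = {d.doc_id for d in docs if d.contains_pair(t)}
        coword_docs[tid] = cw
        for d in docs:
            p = config.base_relevance + (config.coword_boost if d.doc_id in cw else 0.0)
            if rng.random() < min(p, 1.0):
                grade = 2 if rng.random() < config.grade2_fraction else 1
            else:
                grade = 0
            qrels.set(tid, d.doc_id, grade)
    return topics, qrels, coword_docs


def topics_to_xml(topics: Sequence[Topic]) -> bytes:
    root = etree.Element("topics")
    for t in topics:
        el = etree.SubElement(root, "topic", number=t.topic_id)
        etree.SubElement(el, "disease").text = t.disease
        etree.SubElement(el, "gene").text = t.gene_field
        etree.SubElement(el, "demographic").text = t.demographic
        if t.other:
            etree.SubElement(el, "other").text = t.other
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def generate_collection(config: SynthConfig, seed: int) -> dict:
    """End-to-end convenience: corpus + topics + qrels for one seed.

    Returns a dict with parsed ``documents`` (through the production XML
    round trip), ``topics``, ``qrels``, ``coword_docs`` and the raw XML
    bytes of corpus and topics.
    """
    rng = np.random.default_rng(seed)
    docs = generate_documents(config, rng)
    topics, qrels, coword_docs = generate_topics_and_qrels(config, docs, rng)
    corpus_xml = corpus_to_xml(docs)
    return {
        "synth_docs": docs,
        "documents": parse_medline_xml(corpus_xml),
        "topics": topics,
        "qrels": qrels,
        "coword_docs": coword_docs,
        "corpus_xml": corpus_xml,
        "topics_xml": topics_to_xml(topics),
    }
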