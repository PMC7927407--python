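"""Corpus ingestion: MEDLINE-style XML, topics, qrels, TREC run files.

A document contributes two scored surfaces: its abstract (a token sequence
after stop-word removal, of length ``dl``) and its "word list" — the
concatenation of the chemical-substance names, MeSH headings and author
keywords, of length ``dwl = dcl + dml + dkl`` where the three addends count
*terms*, not word tokens. :class:`CorpusIndex` holds the corpus-level
statistics every IDF variant needs plus the posting lists used by the
scoring module.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from ._stopwords import DEFAULT_STOPWORDS

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")

TokenTuple = tuple[str, ...]


class CorpusError(ValueError):
    """Raised for malformed corpus inputs (XML, topics, qrels, runs)."""


def tokenize(text: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Lowercase ``text``, split on non-alphanumerics, drop stop-words.

    Alphanumeric hybrids such as ``v600e`` or ``cdk4`` survive as single
    tokens; hyphens and other punctuation split ("c-mdm2" -> ["c",
    "mdm2"]). Duplicates are preserved so term frequencies stay countable.
    """
    if not text:
        return []
    stop = DEFAULT_STOPWORDS if stopwords is None else frozenset(stopwords)
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in stop]


def normalize_term(term: str, stopwords: Iterable[str] | None = None) -> TokenTuple:
    """Normalize a multi-word term to its token tuple (idempotent)."""
    return tuple(tokenize(term, stopwords))


@dataclass
class Document:
    """One article: abstract tokens plus the three word-list term fields.

    ``*_tokens`` fields hold the per-term normalized token tuples used for
    matching; ``*_terms`` keep the verbatim strings for provenance.
    """

    doc_id: str
    abstract_tokens: tuple[str, ...] = ()
    chemical_terms: tuple[str, ...] = ()
    mesh_terms: tuple[str, ...] = ()
    keyword_terms: tuple[str, ...] = ()
    chemical_tokens: tuple[TokenTuple, ...] = ()
    mesh_tokens: tuple[TokenTuple, ...] = ()
    keyword_tokens: tuple[TokenTuple, ...] = ()

    @classmethod
    def from_fields(
        cls,
        doc_id: str,
        abstract: str = "",
        chemical_terms: Sequence[str] = (),
        mesh_terms: Sequence[str] = (),
        keyword_terms: Sequence[str] = (),
        stopwords: Iterable[str] | None = None,
    ) -> "Document":
        return cls(
            doc_id=str(doc_id),
            abstract_tokens=tuple(tokenize(abstract, stopwords)),
            chemical_terms=tuple(chemical_terms),
            mesh_terms=tuple(mesh_terms),
            keyword_terms=tuple(keyword_terms),
            chemical_tokens=tuple(normalize_term(t, stopwords) for t in chemical_terms),
            mesh_tokens=tuple(normalize_term(t, stopwords) for t in mesh_terms),
            keyword_tokens=tuple(normalize_term(t, stopwords) for t in keyword_terms),
        )

    # field lengths: dl counts abstract tokens, the word-list lengths count terms
    @property
    def dl(self) -> int:
        return len(self.abstract_tokens)

    @property
    def dcl(self) -> int:
        return len(self.chemical_terms)

    @property
    def dml(self) -> int:
        return len(self.mesh_terms)

    @property
    def dkl(self) -> int:
        return len(self.keyword_terms)

    @property
    def dwl(self) -> int:
        return self.dcl + self.dml + self.dkl

    def wordlist_token_tuples(self) -> tuple[TokenTuple, ...]:
        return self.chemical_tokens + self.mesh_tokens + self.keyword_tokens


def _subtuples(tokens: TokenTuple) -> set[str]:
    """All contiguous sub-tuples of a term's tokens, as space-joined keys."""
    n = len(tokens)
    return {" ".join(tokens[i:j]) for i in range(n) for j in range(i + 1, n + 1)}


@dataclass
class CorpusStats:
    """Corpus-level constants feeding the IDF variants.

    ``D`` is the total document count (abstract IDF and, by default, the
    gene IDF); ``n_wordlist`` is the number of documents with ``dwl > 0``
    (the expanded-word IDF's N); ``avgdl``/``avgdwl`` are the mean lengths
    over the corresponding document sets.
    """

    D: int
    avgdl: float
    n_wordlist: int
    avgdwl: float
    df_abstract: dict[str, int] = field(default_factory=dict)
    df_wordlist: dict[str, int] = field(default_factory=dict)
    df_gene: dict[str, int] = field(default_factory=dict)


class CorpusIndex:
    """Inverted index + corpus statistics over a parsed document set."""

    def __init__(self, documents: Sequence[Document]):
        if not documents:
            raise CorpusError("empty corpus")
        self.documents: list[Document] = list(documents)
        self.doc_ids: list[str] = [d.doc_id for d in self.documents]
        self._idx_of = {doc_id: i for i, doc_id in enumerate(self.doc_ids)}

        D = len(self.documents)
        avgdl = sum(d.dl for d in self.documents) / D
        wl_docs = [d for d in self.documents if d.dwl > 0]
        n_wl = len(wl_docs)
        avgdwl = (sum(d.dwl for d in wl_docs) / n_wl) if n_wl else 0.0

        postings: dict[str, dict[int, int]] = {}
        wl_postings: dict[str, set[int]] = {}
        df_any: dict[str, int] = {}
        self._doc_wl_keys: list[frozenset[str]] = []
        # per-document, per-field sub-tuple keys (chemical, mesh, keyword),
        # needed by the within-field co-word mode
        self._doc_field_keys: list[tuple[frozenset[str], ...]] = []
        for i, doc in enumerate(self.documents):
            for tok in doc.abstract_tokens:
                postings.setdefault(tok, {}).setdefault(i, 0)
                postings[tok][i] += 1
            field_keys = []
            for terms in (doc.chemical_tokens, doc.mesh_tokens, doc.keyword_tokens):
                fk: set[str] = set()
                for term in terms:
                    fk |= _subtuples(term)
                fk.discard("")
                field_keys.append(frozenset(fk))
            self._doc_field_keys.append(tuple(field_keys))
            keys = set().union(*field_keys)
            self._doc_wl_keys.append(frozenset(keys))
            for k in keys:
                wl_postings.setdefault(k, set()).add(i)
            # single-token containment anywhere (abstract or word list),
            # used for the gene document frequency
            for tok in set(doc.abstract_tokens) | {k for k in keys if " " not in k}:
                df_any[tok] = df_any.get(tok, 0) + 1

        self._postings = postings
        self._wl_postings = wl_postings
        self._df_any_cache: dict[str, int] = {}
        self.stats = CorpusStats(
            D=D,
            avgdl=avgdl,
            n_wordlist=n_wl,
            avgdwl=avgdwl,
            df_abstract={t: len(p) for t, p in postings.items()},
            df_wordlist={k: len(s) for k, s in wl_postings.items()},
            df_gene=df_any,
        )

    def __len__(self) -> int:
        return len(self.documents)

    def index_of(self, doc_id: str) -> int:
        return self._idx_of[doc_id]

    def tf_abstract(self, term: str, doc_index: int) -> int:
        """Frequency f_i of a query morpheme in a document's abstract."""
        return self._postings.get(term, {}).get(doc_index, 0)

    def postings_abstract(self, term: str) -> Mapping[int, int]:
        return self._postings.get(term, {})

    def wordlist_doc_indices(self, term_tokens: TokenTuple) -> frozenset[int] | set[int]:
        key = " ".join(term_tokens)
        return self._wl_postings.get(key, set())

    def wordlist_contains(self, term_tokens: TokenTuple, doc_index: int) -> bool:
        """True if the term appears contiguously inside one word-list term."""
        return " ".join(term_tokens) in self._doc_wl_keys[doc_index]

    def field_contains(self, term_tokens: TokenTuple, doc_index: int, field_pos: int) -> bool:
        """Containment in one term field (0=chemical, 1=mesh, 2=keyword)."""
        return " ".join(term_tokens) in self._doc_field_keys[doc_index][field_pos]

    def abstract_contains(self, term_tokens: TokenTuple, doc_index: int) -> bool:
        """Contiguous occurrence of a (possibly multi-word) term in an abstract."""
        if len(term_tokens) == 1:
            return doc_index in self._postings.get(term_tokens[0], {})
        toks = self.documents[doc_index].abstract_tokens
        n = len(term_tokens)
        return any(toks[i:i + n] == term_tokens for i in range(len(toks) - n + 1))

    def df_anywhere(self, term_tokens: TokenTuple) -> int:
        """Documents containing the term in the abstract or the word list."""
        if len(term_tokens) == 1:
            return self.stats.df_gene.get(term_tokens[0], 0)
        key = " ".join(term_tokens)
        cached = self._df_any_cache.get(key)
        if cached is not None:
            return cached
        n = sum(
            1 for i in range(len(self.documents))
            if self.abstract_contains(term_tokens, i) or self.wordlist_contains(term_tokens, i)
        )
        self._df_any_cache[key] = n
        return n


def build_index(documents: Sequence[Document]) -> CorpusIndex:
    """Index a document sequence; raises :class:`CorpusError` if empty."""
    return CorpusIndex(documents)


# ---------------------------------------------------------------------------
# MEDLINE-style XML

def parse_medline_xml(source, stopwords: Iterable[str] | None = None) -> list[Document]:
    """Parse MEDLINE/PubMed-dialect XML into :class:`Document` records.

    Reads ``AbstractText`` (multiple fragments are joined),
    ``ChemicalList/Chemical/NameOfSubstance``,
    ``MeshHeadingList/MeshHeading/DescriptorName`` and
    ``KeywordList/Keyword``. Records without a ``PMID`` are skipped with a
    warning; missing fields yield empty sequences and zero lengths.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode())
        else:  # path or file-like
            root = etree.parse(str(source) if isinstance(source, Path) else source).getroot()
    except etree.XMLSyntaxError as exc:
        raise CorpusError(
            f"malformed XML at line {exc.position[0]}, column {exc.position[1]}: {exc}"
        ) from exc

    records = root.findall(".//MedlineCitation")
    if not records:
        records = root.findall(".//Article") or list(root)

    docs: list[Document] = []
    for rec in records:
        pmid = rec.findtext(".//PMID") or rec.get("pmid")
        if not pmid or not pmid.strip():
            logger.warning("skipping record without an identifier")
            continue
        abstract = " ".join(
            (el.text or "") for el in rec.findall(".//AbstractText")
        )
        chem = [el.text or "" for el in rec.findall(".//Chemical/NameOfSubstance")]
        mesh = [el.text or "" for el in rec.findall(".//MeshHeading/DescriptorName")]
        kw = [el.text or "" for el in rec.findall(".//KeywordList/Keyword")]
        docs.append(
            Document.from_fields(
                pmid.strip(), abstract,
                [c for c in chem if c], [m for m in mesh if m], [k for k in kw if k],
                stopwords,
            )
        )
    return docs


# ---------------------------------------------------------------------------
# Topics

@dataclass
class Topic:
    """A precision-medicine topic: disease, gene field, demographics."""

    topic_id: str
    disease: str
    gene_field: str
    demographic: str
    other: str | None = None

    def __post_init__(self) -> None:
        if not self.disease or not self.gene_field:
            raise CorpusError(
                f"topic {self.topic_id}: disease and gene fields are required"
            )
        if self.other is not None and self.other.strip().lower() in {"", "none"}:
            self.other = None


def read_topics(path) -> list[Topic]:
    """Read topics from TREC-PM XML or the JSON fixture dialect.

    XML dialect: ``<topics><topic number="1"><disease>..</disease>
    <gene>..</gene><demographic>..</demographic><other>..</other></topic>
    </topics>``.  JSON dialect: a list of objects with the same keys.
    """
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    topics: list[Topic] = []
    if stripped.startswith("["):
        for obj in json.loads(text):
            topics.append(_topic_from_mapping(obj))
        return topics
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed topics file {path}: {exc}") from exc
    for el in root.findall(".//topic"):
        obj = {"number": el.get("number") or el.findtext("number")}
        for key in ("disease", "gene", "demographic", "other"):
            obj[key] = el.findtext(key)
        topics.append(_topic_from_mapping(obj))
    return topics


def _topic_from_mapping(obj: Mapping) -> Topic:
    tid = str(obj.get("number") or obj.get("topic_id") or "").strip()
    disease = (obj.get("disease") or "").strip()
    gene = (obj.get("gene") or obj.get("gene_field") or "").strip()
    if not disease:
        raise CorpusError(f"topic {tid!r}: missing disease field")
    if not gene:
        raise CorpusError(f"topic {tid!r}: missing gene field")
    return Topic(
        topic_id=tid,
        disease=disease,
        gene_field=gene,
        demographic=(obj.get("demographic") or "").strip(),
        other=obj.get("other"),
    )


# ---------------------------------------------------------------------------
# Qrels

class Qrels:
    """Graded relevance judgments: (topic_id, doc_id) -> grade >= 0."""

    def __init__(self, grades: Mapping[tuple[str, str], int] | None = None):
        self._grades: dict[tuple[str, str], int] = dict(grades or {})

    def __len__(self) -> int:
        return len(self._grades)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._grades

    def set(self, topic_id: str, doc_id: str, grade: int) -> None:
        if grade < 0:
            raise CorpusError(f"negative relevance grade for {topic_id}/{doc_id}")
        self._grades[(str(topic_id), str(doc_id))] = int(grade)

    def grade(self, topic_id: str, doc_id: str) -> int:
        return self._grades.get((str(topic_id), str(doc_id)), 0)

    def topics(self) -> list[str]:
        return sorted({t for t, _ in self._grades})

    def judged(self, topic_id: str) -> dict[str, int]:
        t = str(topic_id)
        return {d: g for (tt, d), g in self._grades.items() if tt == t}

    def relevant(self, topic_id: str, min_grade: int = 1) -> set[str]:
        return {d for d, g in self.judged(topic_id).items() if g >= min_grade}

    def items(self):
        return self._grades.items()


def read_qrels(path) -> Qrels:
    """Parse TREC 4-column qrels ("topic 0 doc grade"); last line wins."""
    qrels = Qrels()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise CorpusError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            topic, _iter, doc, grade_s = parts
            try:
                grade = int(grade_s)
            except ValueError as exc:
                raise CorpusError(
                    f"{path}:{lineno}: non-integer relevance grade {grade_s!r}"
                ) from exc
            if (topic, doc) in qrels:
                logger.warning(
                    "%s:%d: duplicate qrels line for (%s, %s); keeping the later grade",
                    path, lineno, topic, doc,
                )
            qrels.set(topic, doc, grade)
    return qrels


def write_qrels(qrels: Qrels, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (topic, doc), grade in sorted(qrels.items()):
            fh.write(f"{topic} 0 {doc} {grade}\n")


# ---------------------------------------------------------------------------
# Run files

@dataclass
class RunEntry:
    """One ranked result line of a TREC run."""

    topic_id: str
    doc_id: str
    rank: int
    score: float
    tag: str = "cobm25"


def write_trec_run(entries: Sequence[RunEntry], path, tag: str | None = None,
                   top_k: int = 1000) -> None:
    """Write standard 6-column run lines, validating rank/score ordering.

    Scores print with 6 decimals so identical inputs give byte-identical
    files; per topic at most ``top_k`` entries are written.
    """
    by_topic: dict[str, list[RunEntry]] = {}
    for e in entries:
        by_topic.setdefault(e.topic_id, []).append(e)
    lines: list[str] = []
    for topic in by_topic:
        group = sorted(by_topic[topic], key=lambda e: e.rank)[:top_k]
        for pos, e in enumerate(group, 1):
            if e.rank != pos:
                raise CorpusError(
                    f"topic {topic}: ranks not consecutive from 1 (saw {e.rank} at {pos})"
                )
        for a, b in zip(group, group[1:]):
            if b.score > a.score + 1e-12:
                raise CorpusError(
                    f"topic {topic}: score increases with rank ({a.score} -> {b.score})"
                )
        for e in group:
            lines.append(
                f"{e.topic_id} Q0 {e.doc_id} {e.rank} {e.score:.6f} {tag or e.tag}\n"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(lines)


def read_trec_run(path) -> list[RunEntry]:
    entries: list[RunEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise CorpusError(f"{path}:{lineno}: expected 6 columns")
            topic, _q0, doc, rank, score, tag = parts
            entries.append(RunEntry(topic, doc, int(rank), float(score), tag))
    return entries
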