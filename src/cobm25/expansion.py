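"""Query expansion: demographics, gene-field parsing, lexicon lookup.

A precision-medicine topic names a disease, a gene field (possibly with a
variant such as ``BRAF (V600E)`` or a qualifier such as ``CDK4
Amplification``), and a demographic string ("38-year-old male"). Expansion
produces the term sets the scoring model consumes:

* ``abstract_terms`` — morphemes matched against abstracts (BM25 q_i),
* ``wordlist_terms`` — expanded words matched against the chemical/MeSH/
  keyword word list (age and sex categories, "Human", lexicon synonyms),
* ``disease_terms`` / ``gene_terms`` — the pairs driving co-word detection.

Age expands to MeSH-style life-stage categories; the ranges overlap by
design (everyone >= 18 years is also an Adult), so an age may map to
several terms. Synonym expansion uses a static user-supplied lexicon file
rather than a live MeSH lookup, keeping runs hermetic and reproducible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import CorpusError, TokenTuple, Topic, normalize_term

# life-stage term -> [low, high) age range in years, with the two closed
# exceptions handled below (Newborn includes exactly 1 month; Aged 80 and
# Adult are unbounded above)
_MONTH = 1.0 / 12.0
AGE_RANGES: list[tuple[str, float, float]] = [
    ("Newborn", 0.0, _MONTH),          # birth to 1 month, inclusive
    ("Infant", _MONTH, 2.0),           # > 1 month to < 24 months
    ("Preschool", 2.0, 6.0),
    ("Child", 6.0, 13.0),
    ("Adolescent", 13.0, 19.0),
    ("Young", 19.0, 35.0),
    ("Middle Aged", 35.0, 60.0),
    ("Aged", 60.0, 80.0),
    ("Aged 80", 80.0, math.inf),
    ("Adult", 18.0, math.inf),
]


def expand_age(age_years) -> set[str]:
    """Map an age to every life-stage category whose range contains it.

    ``age_years`` may be a number of years or one of the strings
    ``"fetus"`` / ``"newborn"``. Ranges overlap, so e.g. 38 ->
    {"Middle Aged", "Adult"} and 18 -> {"Adolescent", "Adult"}.
    """
    if isinstance(age_years, str):
        token = age_years.strip().lower()
        if token == "fetus":
            return {"Fetus"}
        if token == "newborn":
            return {"Newborn"}
        raise CorpusError(f"unrecognized age token {age_years!r}")
    a = float(age_years)
    if a < 0:
        raise CorpusError(f"negative age {age_years!r}")
    out: set[str] = set()
    for term, lo, hi in AGE_RANGES:
        if term == "Newborn":  # birth to 1 month, both ends included
            if lo <= a <= hi:
                out.add(term)
        elif term == "Infant":  # strictly > 1 month
            if lo < a < hi:
                out.add(term)
        elif lo <= a < hi or (math.isinf(hi) and a >= lo):
            out.add(term)
    return out


_WORD_NUMBERS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11, "twelve": 12,
}
_YEAR_RE = re.compile(r"(\d+(?:\.\d+)?)\s*[- ]\s*year[- ]old", re.I)
_MONTH_RE = re.compile(r"(\d+|[a-z]+)\s*[- ]\s*month[- ]old", re.I)


def parse_demographic(demographic: str) -> tuple[float | str, str | None]:
    """Parse "<N>-year-old <sex>" (or month-old / fetus / newborn) strings.

    Returns ``(age_years, sex)`` where sex is "male", "female" or None.
    """
    s = (demographic or "").strip()
    if not s:
        raise CorpusError("empty demographic string")
    low = s.lower()
    sex = None
    if re.search(r"\bmale\b", low) and not re.search(r"\bfemale\b", low):
        sex = "male"
    elif re.search(r"\bfemale\b", low):
        sex = "female"

    if "fetus" in low or "fetal" in low:
        return "fetus", sex
    if "newborn" in low:
        return "newborn", sex
    m = _YEAR_RE.search(low)
    if m:
        return float(m.group(1)), sex
    m = _MONTH_RE.search(low)
    if m:
        raw = m.group(1)
        months = int(raw) if raw.isdigit() else _WORD_NUMBERS.get(raw)
        if months is None:
            raise CorpusError(f"cannot parse demographic string {demographic!r}")
        return months / 12.0, sex
    raise CorpusError(f"cannot parse demographic string {demographic!r}")


def sex_terms(sex: str | None) -> list[str]:
    """Word-list constants emitted for the patient's sex ('Human' always)."""
    if sex == "male":
        return ["Male", "Human"]
    if sex == "female":
        return ["Female", "Human"]
    return ["Human"]


_QUALIFIERS = {
    "amplification", "fusion", "deletion", "mutation", "mutations",
    "inactivation", "loss", "transposition", "translocation", "rearrangement",
}
_PAREN_RE = re.compile(r"\(([^)]*)\)")


def parse_gene_field(gene_field: str) -> tuple[list[str], list[str]]:
    """Split a topic gene field into gene symbols and variant/qualifier terms.

    ``"BRAF (V600E)"`` -> (["braf"], ["v600e"]); ``"CDK4 Amplification"`` ->
    (["cdk4"], ["amplification"]); comma-separated fields yield several
    genes. Symbols feed co-word detection; variants and qualifiers are kept
    as ordinary query terms only.
    """
    if not gene_field or not gene_field.strip():
        raise CorpusError("empty gene field")
    genes: list[str] = []
    extras: list[str] = []
    for part in re.split(r"[,;]", gene_field):
        part = part.strip()
        if not part:
            continue
        for variant in _PAREN_RE.findall(part):
            for tok in normalize_term(variant, stopwords=()):
                extras.append(tok)
        part = _PAREN_RE.sub(" ", part)
        for tok in normalize_term(part, stopwords=()):
            if tok in _QUALIFIERS:
                extras.append(tok)
            else:
                genes.append(tok)
    if not genes:
        raise CorpusError(f"no gene symbol found in field {gene_field!r}")
    return genes, extras


class ExpansionLexicon:
    """Static term -> expansions mapping (a stand-in for live MeSH lookup).

    Keys are matched case-insensitively after tokenizer normalization.
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]] | None = None):
        self._map: dict[str, list[str]] = {}
        for src, exps in (mapping or {}).items():
            self.add(src, exps)

    def add(self, source: str, expansions: Iterable[str]) -> None:
        key = " ".join(normalize_term(source, stopwords=()))
        bucket = self._map.setdefault(key, [])
        for e in expansions:
            e = e.strip()
            if not e:
                raise CorpusError(f"empty expansion for {source!r}")
            if e not in bucket:
                bucket.append(e)

    def lookup(self, term: str) -> list[str]:
        key = " ".join(normalize_term(term, stopwords=()))
        return list(self._map.get(key, []))

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path) -> "ExpansionLexicon":
        """Load a two-column TSV: source term <TAB> one expansion per row."""
        lex = cls()
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusError(f"{path}:{lineno}: expected 2 tab-separated columns")
            lex.add(parts[0], [parts[1]])
        return lex


def load_builtin_lexicon() -> ExpansionLexicon:
    """The packaged example lexicon (liposarcoma / CDK4-amplification entries)."""
    ref = resources.files("cobm25").joinpath("data/mesh_expansion_example.tsv")
    with resources.as_file(ref) as path:
        return ExpansionLexicon.from_tsv(path)


@dataclass
class ExpandedQuery:
    """A topic after expansion, ready for scoring.

    ``abstract_terms`` are single tokens (duplicates collapsed so each
    query frequency qf_i = 1); ``wordlist_terms`` and ``disease_terms``
    are normalized token tuples (multi-word terms stay contiguous);
    ``gene_terms`` are the gene morphemes used for co-word detection.
    """

    topic_id: str
    abstract_terms: tuple[str, ...]
    wordlist_terms: tuple[TokenTuple, ...]
    disease_terms: tuple[TokenTuple, ...]
    gene_terms: tuple[TokenTuple, ...]

    @property
    def n_wordlist(self) -> int:
        return len(self.wordlist_terms)

    @property
    def n_genes(self) -> int:
        return len(self.gene_terms)


def _dedupe(items: Iterable) -> tuple:
    seen = set()
    out = []
    for it in items:
        if it and it not in seen:
            seen.add(it)
            out.append(it)
    return tuple(out)


def build_expanded_query(
    topic: Topic,
    lexicon: ExpansionLexicon | None = None,
    include_other: bool = True,
    stopwords: Iterable[str] | None = None,
) -> ExpandedQuery:
    """Construct the :class:`ExpandedQuery` for a topic.

    Abstract terms: disease + gene symbols + variants/qualifiers (+ the
    optional "other" condition). Word-list terms: lexicon expansions of the
    disease and gene field, plus age, sex and "Human" constants. Disease
    terms: the disease and its lexicon synonyms. All terms pass through the
    same normalization as documents; duplicates collapse (qf_i = 1).
    """
    lexicon = lexicon or ExpansionLexicon()
    genes, extras = parse_gene_field(topic.gene_field)

    age_sex_terms: list[str] = []
    if topic.demographic:
        age, sex = parse_demographic(topic.demographic)
        age_sex_terms = sorted(expand_age(age)) + sex_terms(sex)

    expansions: list[str] = []
    expansions += lexicon.lookup(topic.disease)
    expansions += lexicon.lookup(topic.gene_field)
    for g in genes:
        expansions += lexicon.lookup(g)

    abstract_source = [topic.disease, topic.gene_field]
    if include_other and topic.other:
        abstract_source.append(topic.other)
    abstract_terms = _dedupe(
        tok for text in abstract_source for tok in normalize_term(text, stopwords)
    )

    wordlist_terms = _dedupe(
        normalize_term(t, stopwords) for t in expansions + age_sex_terms + extras
    )
    disease_terms = _dedupe(
        [normalize_term(topic.disease, stopwords)]
        + [normalize_term(t, stopwords) for t in lexicon.lookup(topic.disease)]
    )
    gene_terms = _dedupe(normalize_term(g, stopwords) for g in genes)
    if not gene_terms:
        raise CorpusError(f"topic {topic.topic_id}: gene terms empty after normalization")
    return ExpandedQuery(
        topic_id=topic.topic_id,
        abstract_terms=abstract_terms,
        wordlist_terms=wordlist_terms,
        disease_terms=disease_terms,
        gene_terms=gene_terms,
    )
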