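# Methods

## The retrieval model

`cobm25` scores a biomedical abstract `d` for a precision-medicine topic
`Q` (a disease, a gene field, patient demographics, optionally another
condition) as a composite of three components:

```
Score(Q,d) = Score_abstract(Q,d) + Score_word(Q,d) + alpha * Score_coword(Q,d)
```

**Abstract score.** Okapi BM25 over the abstract token sequence:

```
Score_abstract = sum_i  ln(D / df_i) * f_i (k1+1) / (f_i + K)
K = k1 * (1 - b1 + b1 * dl / avgdl)
```

where `f_i` is the frequency of query morpheme `q_i` in the abstract,
`dl` the abstract length after stop-word removal, `avgdl` its corpus
mean, and `df_i` the morpheme's document frequency. Query morphemes are
deduplicated at expansion time, so every query frequency is 1 and the
classical `(k2+1)qf/(qf+k2)` factor is identically 1; `k2` is kept in the
parameter object for completeness but never searched.

**Expanded-word score.** Each document's chemical substances, MeSH
headings and author keywords form its *word list* of length
`dwl = dcl + dml + dkl` (terms, not word tokens — a heading like
"Cyclin-Dependent Kinase 4" counts once). The query's expanded words
(lexicon synonyms, life-stage/sex terms, variant and qualifier tokens)
are matched against it, and the matches' Robertson–Spärck-Jones IDFs are
summed into a pseudo-frequency:

```
tf_word = sum over matching expanded words of  ln((N - n + 0.5) / (n + 0.5))
Score_word = tf_word (k3+1) / (tf_word + k3 (1 - b2 + b2 * dwl / avgdwl))
```

with `N` the number of documents having a non-empty word list and `n` the
word's document frequency within those. Note that `tf_word` is a sum of
IDFs, not of occurrence counts; the component therefore rewards *how many
and how rare* the matched expansions are. Its BM25-style saturation is
bounded by `k3 + 1` for non-negative `tf_word`. RSJ IDFs go negative for
words present in more than half of the word-list documents; they are
preserved as such by default (`floor_zero` restores the common
non-negative variant). A negative `tf_word` can make this component
behave pathologically (the denominator may approach zero); with the
default sign-preserving behavior, callers should expand with reasonably
specific terms.

**Co-word score.** A gene `g_i` of the topic "co-words" with the disease
in document `d` when both occur in `d`'s fields. Two detection modes:

* `cross` (default): disease anywhere in the four fields (abstract,
  chemical, MeSH, keyword) *and* gene anywhere in the four fields;
* `within`: disease and gene inside the *same* field. Every within-mode
  match is also a cross-mode match.

The score sums `ln((N - n(g_i) + 0.5) / (n(g_i) + 0.5))` over the matched
genes, with `N` the total document count `D` (a flag switches to the
word-list-restricted count) and `n(g_i)` the number of documents carrying
the gene anywhere. Matching is contiguous token-subsequence matching on
normalized terms: multi-word disease names must appear contiguously, and
token substrings never match (RAS does not match KRAS).

**Normalization.** One tokenizer serves documents and queries:
lowercase, split at non-alphanumerics (hybrids like `v600e` survive as
single tokens), stop-words removed using a packaged standard English list
(configurable). Log base is natural everywhere; it rescales scores
uniformly and cancels inside nDCG.

**Smoothing and degenerate inputs.** Abstract IDF floors `df` at 1 so
out-of-corpus terms stay finite. Documents without an abstract are
indexed (they can match via the word list) and score 0 on the abstract
component; `dwl = 0` documents score 0 on the word component. An empty
corpus and a corpus with no word lists raise errors rather than guessing.

## Query expansion

The gene field splits into gene symbols and variant/qualifier tokens
(`"BRAF (V600E)"` → gene `braf`, variant `v600e`; `"CDK4 Amplification"`
→ gene `cdk4`, qualifier `amplification`). Variants and qualifiers join
the abstract and word-list terms but are excluded from co-word detection,
which keys on gene symbols — co-occurrence figures at gene level, not
variant level. The demographic string parses to an age and sex; ages map
to overlapping life-stage ranges (Newborn ≤ 1 month; Infant > 1 to < 24
months; Preschool 2–<6; Child 6–<13; Adolescent 13–<19; Young 19–<35;
Middle Aged 35–<60; Aged 60–<80; Aged 80 ≥ 80; Adult ≥ 18), so 38 →
{Middle Aged, Adult} and 18 → {Adolescent, Adult}. Sex adds
Male/Female plus Human. Synonym expansion uses a static two-column TSV
lexicon supplied by the user (a small example covering the
liposarcoma/CDK4 topic ships with the package); there is deliberately no
live terminology-service lookup, so runs are hermetic. The optional
"other" condition of a topic joins the abstract terms by default and can
be switched off.

## Evaluation

Per topic: P@10 (denominator fixed at 10 even for short result lists),
nDCG at the run depth with linear gains `gain(grade) = grade` by default
(exponential `2^g - 1` by flag) and the ideal list built from *all*
judged documents, R-precision, precision/recall/F1 at the run cutoff, and
the co-word coverage rate — the fraction of a topic's relevant documents
that are co-word documents, averaged over topics (topics without relevant
documents are excluded with a warning). Relevance is binary at grade ≥ 1
for the set-based metrics. Averages are over all topics in the qrels;
topics missing from a run contribute 0.

## Parameter tuning

`(k1, k3, b1, b2, alpha)` maximize `Avg P@10 + Avg nDCG` (range [0, 2])
by Cuckoo Search over bounds `(0,100)^2 x (0,1)^2 x (0,5)`. Defaults:
40 nests, step size T = 1, 500 generations, abandonment probability
Pa = 0.25, Lévy exponent 1.5 — Pa and the exponent follow the method's
standard settings; the rest is configurable. Each generation every nest
emits an egg displaced by a Mantegna Lévy step scaled by
`T * 0.01 * (X_i - X_best)` (the reference implementation's scaling; it
lets steps shrink as the swarm converges — an unscaled fixed step cannot
refine past its own scale), eggs replace a random nest only if fitter,
non-best nests are abandoned with probability Pa and redrawn uniformly,
and the best nest always survives, making the best-so-far trace monotone.
Out-of-bound proposals are clamped (reflection available). For the Lévy
exponent the Mantegna stability index equals the exponent below 2 and
steps degenerate to Gaussian at and above 2; the accepted range is
(1, 3]. Objective values are memoized on vectors quantized at 1e-9 —
the ranking is deterministic, so re-evaluation is pure cost. Everything
is reproducible from one integer seed.

The retrieval objective precomputes, per topic, the parameter-independent
pieces (per-term postings and IDFs, `tf_word`, the co-word score), so one
objective evaluation is a handful of numpy operations per topic; a
reduced search (15 nests, 50 generations, 500 documents, 10 topics) runs
in about a second.

## Synthetic collections

The generator emulates the *shape* of a MEDLINE-scale corpus, not its
language: Zipf-distributed symbols (exponent 1.1), Poisson field lengths
with means 77.5 (abstract tokens) and 3.8 / 10.5 / 4.1 (chemical / MeSH /
keyword terms, present in 49% / 92% / 15% of documents) matching the
published corpus statistics. MeSH lists carry demographic check-tags
(Human, sex, life stage) within the same length budget, kept below half
the word-list documents so expanded-word IDFs keep their usual positive
sign. Per topic a disease and gene symbol are planted as a co-occurring
pair into a fraction of documents (default 15% across 10 topics), placed
within one field or across two fields with equal probability so the two
co-word modes separate; another 10% of documents get only one half of a
pair, making co-occurrence genuinely discriminative. Relevance grades
{0,1,2} are drawn with `P(relevant) = 0.01 + 0.7 * 1[pair present]`
(grade 2 with probability 0.3 given relevant); these defaults put the
co-word coverage rate near 50% and P@10 near 0.6, the regime reported
for real precision-medicine collections. What passing tests on this
fixture show is that the machinery is correct and that the co-word
component is recovered when co-occurrence truly drives relevance; they
cannot show that real MEDLINE relevance behaves this way.

## Numerical choices

Ranking ties break on ascending document id, exactly and reproducibly.
Run files print scores at 6 decimals and are byte-stable. The scoring
decomposition `composite = abstract + word + alpha*coword` is asserted as
an exact identity, not to tolerance. Duplicate qrels lines: the last one
wins, with a warning.

## Known limitations

* `tf_word` is a sum of IDFs as defined; occurrence counts within the
  word list never enter.
* No phrase or proximity scoring beyond contiguous multi-word terms; no
  title-field scoring; no relevance feedback; no live MeSH expansion.
* The inferred variant of nDCG over sampled judgment pools is not
  implemented; outputs are labelled nDCG and computed from full qrels.
* The optimizer's only stop criterion is the generation cap.
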