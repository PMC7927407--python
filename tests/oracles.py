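"""Independent straight-line reference implementations used by the tests.

Everything here recomputes quantities from first principles with plain
loops and no index structures, deliberately sharing no code with the
package: document frequencies come from per-document membership scans,
the ranking metrics are textbook transcriptions (nDCG in base-2 logs,
which must agree with the package's natural-log ratio).
"""

import math


def _dwl(doc):
    return doc.dcl + doc.dml + doc.dkl


def _term_in_termfield(term, field_tokens):
    n = len(term)
    for ft in field_tokens:
        for i in range(len(ft) - n + 1):
            if tuple(ft[i:i + n]) == tuple(term):
                return True
    return False


def _term_in_abstract(term, abstract):
    n = len(term)
    for i in range(len(abstract) - n + 1):
        if tuple(abstract[i:i + n]) == tuple(term):
            return True
    return False


def _in_wordlist(term, doc):
    return (
        _term_in_termfield(term, doc.chemical_tokens)
        or _term_in_termfield(term, doc.mesh_tokens)
        or _term_in_termfield(term, doc.keyword_tokens)
    )


def _presence(term, doc):
    return [
        _term_in_abstract(term, doc.abstract_tokens),
        _term_in_termfield(term, doc.chemical_tokens),
        _term_in_termfield(term, doc.mesh_tokens),
        _term_in_termfield(term, doc.keyword_tokens),
    ]


def _anywhere(term, doc):
    return any(_presence(term, doc))


def oracle_breakdown(query, documents, doc, params, mode="cross"):
    """(abstract, word, coword, composite) scores by brute force."""
    D = len(documents)
    avgdl = sum(d.dl for d in documents) / D

    sa = 0.0
    if doc.dl > 0:
        for q in query.abstract_terms:
            f = list(doc.abstract_tokens).count(q)
            if f == 0:
                continue
            df = sum(1 for d2 in documents if q in d2.abstract_tokens)
            idf = math.log(D / max(df, 1))
            K = params.k1 * (1 - params.b1 + params.b1 * doc.dl / avgdl)
            sa += idf * f * (params.k1 + 1) / (f + K)

    wl_docs = [d for d in documents if _dwl(d) > 0]
    N = len(wl_docs)
    sw = 0.0
    if N > 0 and _dwl(doc) > 0:
        avgdwl = sum(_dwl(d) for d in wl_docs) / N
        tf = 0.0
        for t in query.wordlist_terms:
            if _in_wordlist(t, doc):
                n = sum(1 for d2 in wl_docs if _in_wordlist(t, d2))
                tf += math.log((N - n + 0.5) / (n + 0.5))
        if tf != 0.0:
            sw = tf * (params.k3 + 1) / (
                tf + params.k3 * (1 - params.b2 + params.b2 * _dwl(doc) / avgdwl)
            )

    disease_fields = [False] * 4
    for dt in query.disease_terms:
        for i, hit in enumerate(_presence(dt, doc)):
            disease_fields[i] = disease_fields[i] or hit
    sc = 0.0
    for g in query.gene_terms:
        gp = _presence(g, doc)
        if mode == "cross":
            matched = any(disease_fields) and any(gp)
        else:
            matched = any(d and gg for d, gg in zip(disease_fields, gp))
        if matched:
            n = sum(1 for d2 in documents if _anywhere(g, d2))
            sc += math.log((D - n + 0.5) / (n + 0.5))

    return sa, sw, sc, sa + sw + params.alpha * sc


# ---------------------------------------------------------------------------
# metric references (base-2 logs; nDCG is base-invariant)

def oracle_precision_at_k(ranked, judged, k):
    return sum(1 for d in ranked[:k] if judged.get(d, 0) >= 1) / k


def oracle_ndcg(ranked, judged, z, gain=lambda g: float(g)):
    ideal = sorted((gain(g) for g in judged.values()), reverse=True)[:z]
    dcg_i = sum(g / math.log2(i + 2) for i, g in enumerate(ideal))
    if dcg_i == 0:
        return 0.0
    dcg = sum(
        gain(judged.get(d, 0)) / math.log2(i + 2)
        for i, d in enumerate(ranked[:z])
    )
    return dcg / dcg_i


def oracle_r_precision(ranked, judged):
    R = sum(1 for g in judged.values() if g >= 1)
    if R == 0:
        return 0.0
    return sum(1 for d in ranked[:R] if judged.get(d, 0) >= 1) / R


def oracle_recall_f1(ranked, judged):
    relevant = {d for d, g in judged.items() if g >= 1}
    rr = sum(1 for d in ranked if d in relevant)
    p = rr / len(ranked) if ranked else 0.0
    r = rr / len(relevant) if relevant else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return r, f1


def oracle_coverage(relevant_by_topic, coword_by_topic):
    rates = [
        len(rel & coword_by_topic.get(t, set())) / len(rel)
        for t, rel in relevant_by_topic.items() if rel
    ]
    return sum(rates) / len(rates)
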