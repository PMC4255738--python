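"""Bag-of-words construction, tf-idf weighting, trimming and the DB."""

from __future__ import annotations

import math
import random
from collections import Counter

import pytest

from corpusrel.corpus import Document
from corpusrel.tgsp import PhraseCandidate
from corpusrel.vectorizer import (
    BagOfWords,
    BuildConfig,
    IdfTable,
    SparseVector,
    VectorDB,
    bow_from_document,
    bow_from_phrases,
    build_vector_db,
    compute_idf,
    tfidf_vector,
    trim_vector_topk,
)

KEPT = [PhraseCandidate(("cancer", "patient"), 2), PhraseCandidate(("cancer",), 3)]


def test_bow_from_phrases_bow_source_sums_containing_phrases():
    bow = bow_from_phrases(KEPT, [], tf_source="bow", stopwords=frozenset())
    assert bow.counts == {"cancer": 5, "patient": 2}


def test_bow_from_phrases_document_source_uses_raw_frequency():
    doc_tokens = ["cancer"] * 7 + ["patient"] * 2 + ["noise"] * 3
    bow = bow_from_phrases(KEPT, doc_tokens, tf_source="document", stopwords=frozenset())
    assert bow.counts == {"cancer": 7, "patient": 2}


def test_bow_from_phrases_empty_and_stopwords():
    assert bow_from_phrases([], [], "bow").counts == {}
    kept = [PhraseCandidate(("treatment", "of", "tumors"), 4)]
    bow = bow_from_phrases(kept, [], "bow", stopwords=frozenset({"of"}))
    assert bow.counts == {"treatment": 4, "tumors": 4}


def test_bow_from_document_counts():
    assert bow_from_document(["a", "b", "a"]).counts == {"a": 2, "b": 1}
    assert bow_from_document([]).counts == {}
    tokens = "the quick brown fox jumps over the lazy dog the end".split()
    assert bow_from_document(tokens).counts == dict(Counter(tokens))


def test_compute_idf_arithmetic():
    # 100 bags, 9 of them containing "rare": idf = ln(100/10) = ln 10
    bows = [BagOfWords({"rare": 1} if i < 9 else {"common": 1}) for i in range(100)]
    table = compute_idf(bows)
    assert table.values["rare"] == pytest.approx(math.log(10), abs=1e-12)
    # a term in every bag gets a negative idf: ln(n/(n+1))
    bows = [BagOfWords({"ubiquitous": 1}) for _ in range(10)]
    table = compute_idf(bows)
    assert table.values["ubiquitous"] == pytest.approx(math.log(10 / 11), abs=1e-12)
    with pytest.raises(ValueError):
        compute_idf([])


def test_compute_idf_matches_brute_force_on_random_collections():
    rng = random.Random(20240401)
    for _ in range(100):
        n = rng.randint(1, 12)
        bows = [
            BagOfWords({f"w{rng.randint(0, 8)}": rng.randint(1, 4)
                        for _ in range(rng.randint(0, 6))})
            for _ in range(n)
        ]
        table = compute_idf(bows)
        for term, value in table.values.items():
            df = sum(1 for b in bows if term in b.counts)
            assert value == pytest.approx(math.log(n / (df + 1)), abs=1e-12)
            assert table.df[term] == df


def test_tfidf_vector_positive_only_and_vocab_modes():
    idf = IdfTable(doc_count=4, df={}, values={"a": 2.0, "b": 3.0, "z": 0.0})
    vocab: dict[str, int] = {}
    v = tfidf_vector(BagOfWords({"a": 2, "b": 1}), idf, vocab)
    assert v.entries == {vocab["a"]: 4.0, vocab["b"]: 3.0}
    # zero idf and empty bows produce empty vectors
    assert tfidf_vector(BagOfWords({"z": 2}), idf, vocab).is_zero()
    assert tfidf_vector(BagOfWords({}), idf, vocab).is_zero()
    # unknown term: extends the vocab at build time, dropped at query time
    before = dict(vocab)
    q = tfidf_vector(BagOfWords({"new": 1}), IdfTable(1, {}, {"new": 1.0}),
                     dict(before), extend_vocab=False)
    assert q.is_zero()


def test_sparse_vector_rejects_non_positive_weights():
    with pytest.raises(ValueError):
        SparseVector(entries={0: -1.0})
    with pytest.raises(ValueError):
        SparseVector(entries={0: 0.0})


def _vec(weights):
    return SparseVector(entries=dict(enumerate(weights)), dimensionality=len(weights))


def test_trim_vector_topk_examples():
    v = _vec([3.0, 2.0, 1.0, 0.5])
    assert trim_vector_topk(v, 0.5).entries == {0: 3.0, 1: 2.0}
    assert trim_vector_topk(v, 1.0).entries == v.entries
    single = _vec([4.2])
    assert trim_vector_topk(single, 0.05).entries == {0: 4.2}  # ceiling >= 1
    assert trim_vector_topk(SparseVector(), 0.3).is_zero()
    for bad in (0.0, 1.0001, -2):
        with pytest.raises(ValueError):
            trim_vector_topk(v, bad)


def test_trim_vector_topk_tie_break_prefers_low_index():
    v = SparseVector(entries={5: 2.0, 1: 2.0, 3: 2.0, 7: 1.0}, dimensionality=8)
    assert set(trim_vector_topk(v, 0.5).entries) == {1, 3}


def test_build_plain_c1_is_untrimmed_tfidf(fixture_docs):
    docs = fixture_docs[:5]
    db = build_vector_db(docs, BuildConfig(variant="plain", c=1.0))
    # reproduce the untrimmed pipeline by hand for each document
    from corpusrel.corpus import tokenize

    bows = [bow_from_document(tokenize(d.text())) for d in docs]
    idf = compute_idf(bows)
    vocab: dict[str, int] = {}
    for d, bow in zip(docs, bows):
        expected = tfidf_vector(bow, idf, vocab)
        assert db.vectors[d.doc_id].entries == expected.entries


def test_build_reports_and_skips_unreadable_documents(fixture_docs):
    class Broken:
        doc_id = "broken"

        def text(self, mode):
            raise IOError("unreadable")

    docs = list(fixture_docs[:4]) + [Broken()]
    db = build_vector_db(docs, BuildConfig(variant="plain", c=0.5))
    assert db.report.n_documents == 4
    assert db.report.n_skipped == 1
    assert db.report.skipped_ids == ["broken"]


def test_all_stored_weights_strictly_positive(db_plain, db_tgsp):
    for db in (db_plain, db_tgsp):
        for v in db.vectors.values():
            assert all(w > 0 for w in v.entries.values())


def test_mean_vector_size_non_decreasing_in_c(dbs_by_c):
    sizes = [dbs_by_c[c].mean_vector_size() for c in (0.05, 0.1, 0.2, 0.4)]
    assert sizes == sorted(sizes)


def test_tgsp_per_document_stage_is_corpus_independent(fixture_docs):
    """Everything before the idf pass uses only the document itself, so a
    document's trimmed bag is identical whether its corpus has 5 or 50
    documents."""
    from corpusrel.corpus import tokenize
    from corpusrel.tgsp import default_tagger, extract_candidates, pos_tag, trim_phrase_table

    def doc_bag(doc):
        tokens = tokenize(doc.text())
        tagged = pos_tag(tokens, default_tagger())
        kept = trim_phrase_table(extract_candidates(tagged), 0.5)
        return bow_from_phrases(kept, tokens, "bow").counts

    target = fixture_docs[0]
    bag_alone = doc_bag(target)
    db_small = build_vector_db(fixture_docs[:5], BuildConfig(variant="tgsp", c=0.5))
    db_large = build_vector_db(fixture_docs[:50], BuildConfig(variant="tgsp", c=0.5))

    def recover_bag(db):
        inv = {i: t for t, i in db.vocab.items()}
        v = db.vectors[target.doc_id]
        return {inv[i]: w / db.idf_table.values[inv[i]] for i, w in v.entries.items()}

    for db in (db_small, db_large):
        bag = recover_bag(db)
        # stored tf (weight / idf) must match the standalone bag wherever idf > 0
        for term, tf in bag.items():
            assert tf == pytest.approx(bag_alone[term])


def test_vector_db_round_trip_bit_identical(tmp_path, db_plain):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    db_plain.save(d1)
    reloaded = VectorDB.load(d1)
    reloaded.save(d2)
    for name in ("db_meta.json", "vocab.tsv", "vectors.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    assert reloaded.vectors["t0d000"].entries == db_plain.vectors["t0d000"].entries
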