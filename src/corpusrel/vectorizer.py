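"""Document vectorization: tf-idf sparse vectors and the vector database.

Each corpus document is reduced to a sparse positive-weight vector in a
shared vocabulary space, under one of two variants:

* ``tgsp`` — the document's trimmed key-phrase table is tokenized into a
  bag of words; term frequencies come either from the phrase table
  (``tf_source="bow"``) or from the raw document (``tf_source="document"``).
  The idf statistics are computed over the collection of trimmed
  key-phrase bags, after trimming — no cross-document statistic enters the
  pipeline before that point, which keeps per-document preprocessing
  embarrassingly parallel.
* ``plain`` — the raw token counts of the document are weighted directly,
  and each vector is then cut to its top-weight fraction ``c`` of stored
  dimensions.

Weights follow tfidf(t, d, D) = tf(t, d) * ln(|D| / (df(t) + 1)); only
strictly positive weights are stored (a term occurring in every bag has a
negative idf and simply disappears from the space).

The resulting :class:`VectorDB` persists as plain-text TSV (vocabulary and
vector records) plus a JSON header, and reloads bit-identically: float
weights are serialized with ``repr``, which round-trips IEEE doubles
exactly.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .corpus import DEFAULT_STOPWORDS, Document, TokenStream, tokenize
from . import tgsp as _tgsp
from .tgsp import PhraseCandidate, default_tagger

__all__ = [
    "BagOfWords",
    "IdfTable",
    "SparseVector",
    "BuildConfig",
    "BuildReport",
    "VectorDB",
    "bow_from_phrases",
    "bow_from_document",
    "compute_idf",
    "tfidf_vector",
    "trim_vector_topk",
    "build_vector_db",
]


@dataclass
class BagOfWords:
    """Term -> positive count multiset representing one document."""

    counts: dict[str, int] = field(default_factory=dict)
    source_doc: str = ""


@dataclass
class IdfTable:
    """Document frequencies and idf values over a bag-of-words collection."""

    doc_count: int
    df: dict[str, int]
    values: dict[str, float]


@dataclass
class SparseVector:
    """Positive-weight (dimension index -> value) map.

    ``dimensionality`` records the size of the shared vocabulary the
    indices live in; it is informational and may lag behind a vocabulary
    that grew after the vector was built.
    """

    entries: dict[int, float] = field(default_factory=dict)
    dimensionality: int = 0

    def __post_init__(self) -> None:
        for idx, value in self.entries.items():
            if value <= 0:
                raise ValueError(f"non-positive stored weight at dim {idx}: {value}")

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.entries.values()))

    def is_zero(self) -> bool:
        return not self.entries

    def __len__(self) -> int:
        return len(self.entries)


def bow_from_phrases(
    kept: Sequence[PhraseCandidate],
    doc_tokens: TokenStream | Sequence[str],
    tf_source: str = "bow",
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> BagOfWords:
    """Tokenize a trimmed phrase table into a unigram bag of words.

    ``tf_source="bow"`` sums the frequencies of the kept phrases containing
    each term; ``tf_source="document"`` takes the term's raw frequency in
    the original document. Stopwords inside phrases are dropped.
    """
    if tf_source not in ("bow", "document"):
        raise ValueError(f"unknown tf_source: {tf_source!r}")
    counts: dict[str, int] = {}
    if tf_source == "bow":
        for cand in kept:
            for term in sorted(set(cand.phrase)):
                if term in stopwords:
                    continue
                counts[term] = counts.get(term, 0) + cand.frequency
    else:
        doc_counts = Counter(doc_tokens)
        terms = {t for cand in kept for t in cand.phrase if t not in stopwords}
        for term in sorted(terms):
            tf = doc_counts.get(term, 0)
            if tf > 0:
                counts[term] = tf
    return BagOfWords(counts=counts)


def bow_from_document(doc_tokens: TokenStream | Sequence[str], source_doc: str = "") -> BagOfWords:
    """Raw token-frequency bag of the document itself (plain variant)."""
    return BagOfWords(counts=dict(Counter(doc_tokens)), source_doc=source_doc)


def compute_idf(bows: Sequence[BagOfWords]) -> IdfTable:
    """idf(t, D) = ln(|D| / (df(t) + 1)) over the given bag collection."""
    if not bows:
        raise ValueError("cannot compute idf over an empty collection")
    doc_count = len(bows)
    df: Counter[str] = Counter()
    for bow in bows:
        df.update(bow.counts.keys())
    values = {t: math.log(doc_count / (n + 1)) for t, n in df.items()}
    return IdfTable(doc_count=doc_count, df=dict(df), values=values)


def tfidf_vector(
    bow: BagOfWords,
    idf_table: IdfTable,
    vocab: dict[str, int],
    extend_vocab: bool = True,
) -> SparseVector:
    """tf * idf weights for a bag; only strictly positive weights stored.

    Terms absent from ``vocab`` are appended to it when ``extend_vocab``
    (build phase) or silently dropped (query phase). Terms absent from the
    idf table are always dropped.
    """
    entries: dict[int, float] = {}
    for term in sorted(bow.counts):
        idf = idf_table.values.get(term)
        if idf is None:
            continue
        weight = bow.counts[term] * idf
        if weight <= 0:
            continue
        if term not in vocab:
            if not extend_vocab:
                continue
            vocab[term] = len(vocab)
        entries[vocab[term]] = weight
    return SparseVector(entries=entries, dimensionality=len(vocab))


def trim_vector_topk(v: SparseVector, fraction: float) -> SparseVector:
    """Keep the ceil(fraction * nnz) largest-weight entries of ``v``.

    Ties on weight are resolved toward the lower dimension index. A
    non-empty vector always retains at least one entry.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not v.entries:
        return SparseVector(entries={}, dimensionality=v.dimensionality)
    keep = math.ceil(fraction * len(v.entries))
    ranked = sorted(v.entries.items(), key=lambda kv: (-kv[1], kv[0]))[:keep]
    return SparseVector(entries=dict(ranked), dimensionality=v.dimensionality)


@dataclass(frozen=True)
class BuildConfig:
    """Vector database build parameters.

    ``variant`` selects the preprocessing route, ``c`` is the trimming
    threshold (cumulative phrase-frequency fraction for ``tgsp``,
    top-weight dimension fraction for ``plain``), ``tf_source`` applies to
    the ``tgsp`` variant only.
    """

    variant: str = "plain"
    c: float = 0.05
    tf_source: str = "bow"
    section_mode: str = "full"
    window: int = _tgsp.DEFAULT_WINDOW
    grammars: tuple[tuple[str, ...], ...] = _tgsp.DEFAULT_GRAMMARS

    def __post_init__(self) -> None:
        if self.variant not in ("plain", "tgsp"):
            raise ValueError(f"unknown variant: {self.variant!r}")
        if not 0 < self.c <= 1:
            raise ValueError(f"threshold c must be in (0, 1], got {self.c}")


@dataclass
class BuildReport:
    n_documents: int = 0
    n_skipped: int = 0
    skipped_ids: list[str] = field(default_factory=list)


@dataclass
class VectorDB:
    """Persistent doc_id -> sparse vector store with shared vocabulary."""

    vectors: dict[str, SparseVector]
    vocab: dict[str, int]
    idf_table: IdfTable
    config: BuildConfig
    report: BuildReport = field(default_factory=BuildReport)

    def mean_vector_size(self) -> float:
        """Mean stored entries per vector (the DB-size statistic)."""
        if not self.vectors:
            return 0.0
        return sum(len(v) for v in self.vectors.values()) / len(self.vectors)

    def save(self, dirpath: str | Path) -> None:
        d = Path(dirpath)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "variant": self.config.variant,
            "c": self.config.c,
            "tf_source": self.config.tf_source,
            "section_mode": self.config.section_mode,
            "window": self.config.window,
            "grammars": [list(g) for g in self.config.grammars],
            "doc_count": self.idf_table.doc_count,
            "n_documents": self.report.n_documents,
            "n_skipped": self.report.n_skipped,
        }
        (d / "db_meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")
        index_to_term = {i: t for t, i in self.vocab.items()}
        with open(d / "vocab.tsv", "w", encoding="utf-8") as fh:
            for i in range(len(index_to_term)):
                term = index_to_term[i]
                df = self.idf_table.df.get(term, 0)
                idf = self.idf_table.values.get(term, 0.0)
                fh.write(f"{term}\t{i}\t{df}\t{idf!r}\n")
        with open(d / "vectors.tsv", "w", encoding="utf-8") as fh:
            for doc_id in sorted(self.vectors):
                v = self.vectors[doc_id]
                cells = " ".join(f"{i}:{v.entries[i]!r}" for i in sorted(v.entries))
                fh.write(f"{doc_id}\t{cells}\n")

    @classmethod
    def load(cls, dirpath: str | Path) -> "VectorDB":
        d = Path(dirpath)
        meta = json.loads((d / "db_meta.json").read_text())
        config = BuildConfig(
            variant=meta["variant"],
            c=meta["c"],
            tf_source=meta["tf_source"],
            section_mode=meta["section_mode"],
            window=meta["window"],
            grammars=tuple(tuple(g) for g in meta["grammars"]),
        )
        vocab: dict[str, int] = {}
        df: dict[str, int] = {}
        values: dict[str, float] = {}
        with open(d / "vocab.tsv", encoding="utf-8") as fh:
            for line in fh:
                term, idx, dfreq, idf = line.rstrip("\n").split("\t")
                vocab[term] = int(idx)
                df[term] = int(dfreq)
                values[term] = float(idf)
        dim = len(vocab)
        vectors: dict[str, SparseVector] = {}
        with open(d / "vectors.tsv", encoding="utf-8") as fh:
            for line in fh:
                doc_id, _, cells = line.rstrip("\n").partition("\t")
                entries = {}
                if cells:
                    for cell in cells.split(" "):
                        i, val = cell.split(":", 1)
                        entries[int(i)] = float(val)
                vectors[doc_id] = SparseVector(entries=entries, dimensionality=dim)
        idf_table = IdfTable(doc_count=meta["doc_count"], df=df, values=values)
        report = BuildReport(n_documents=meta["n_documents"], n_skipped=meta["n_skipped"])
        return cls(vectors=vectors, vocab=vocab, idf_table=idf_table, config=config, report=report)


def build_vector_db(
    documents: Iterable[Document],
    config: BuildConfig = BuildConfig(),
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    tagger: Callable[[str], str] | None = None,
) -> VectorDB:
    """Run the per-document preprocessing pipeline and assemble the DB.

    Per-document stages are independent until the idf pass; idf is
    computed over the (trimmed, for ``tgsp``) bag collection, then vectors
    are weighted and, for the ``plain`` variant, cut to their top-weight
    fraction. Documents whose processing raises are skipped and counted in
    the build report.
    """
    tagger = tagger or default_tagger()
    report = BuildReport()
    bows: list[BagOfWords] = []
    doc_ids: list[str] = []
    seen: set[str] = set()
    for doc in documents:
        try:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
            tokens = tokenize(doc.text(config.section_mode), stopwords)
            if config.variant == "tgsp":
                tagged = _tgsp.pos_tag(tokens, tagger)
                table = _tgsp.extract_candidates(tagged, config.grammars, config.window)
                kept = _tgsp.trim_phrase_table(table, config.c)
                bow = bow_from_phrases(kept, tokens, config.tf_source, stopwords)
            else:
                bow = bow_from_document(tokens)
            bow.source_doc = doc.doc_id
        except Exception:
            report.n_skipped += 1
            report.skipped_ids.append(getattr(doc, "doc_id", "<unknown>"))
            continue
        seen.add(doc.doc_id)
        bows.append(bow)
        doc_ids.append(doc.doc_id)
        report.n_documents += 1
    if not bows:
        raise ValueError("no readable documents; cannot build a vector database")
    idf_table = compute_idf(bows)
    vocab: dict[str, int] = {}
    vectors: dict[str, SparseVector] = {}
    for doc_id, bow in zip(doc_ids, bows):
        v = tfidf_vector(bow, idf_table, vocab, extend_vocab=True)
        if config.variant == "plain":
            v = trim_vector_topk(v, config.c)
        vectors[doc_id] = v
    dim = len(vocab)
    for v in vectors.values():
        v.dimensionality = dim
    return VectorDB(vectors=vectors, vocab=vocab, idf_table=idf_table, config=config, report=report)
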