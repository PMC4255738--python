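"""Inverted index with ranked least-restrictive boolean retrieval.

The index serves the first runtime step of the relatedness method:
finding the most relevant documents for a free-text label. Multi-term
queries are parsed as an OR over their tokens (the least restrictive
boolean reading), so the candidate set is every document containing at
least one query token. Candidates are ranked by a conventional
length-normalized tf-idf score

    score(q, d) = (1 / sqrt(|d|)) * sum_{t in q} tf(t, d) * idf(t, D)

with idf(t, D) = ln(|D| / (df(t) + 1)). Ties are broken by ascending
document id so retrieval is reproducible across runs and machines.

Persistence is plain text (sorted TSV plus a JSON header); rebuilding the
index from identical inputs produces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .corpus import DEFAULT_STOPWORDS, Document, TokenStream, tokenize

__all__ = ["CorpusIndex", "DuplicateDocumentError", "build_index"]


class DuplicateDocumentError(ValueError):
    """Raised when two ingested documents share a doc_id."""


@dataclass
class CorpusIndex:
    """Term -> {doc_id: term frequency} postings over a fixed corpus.

    ``doc_lengths`` holds the post-stopword token count of each document,
    used for length normalization of retrieval scores.
    """

    doc_count: int = 0
    postings: dict[str, dict[str, int]] = field(default_factory=dict)
    doc_lengths: dict[str, int] = field(default_factory=dict)
    section_mode: str = "full"
    stopwords: frozenset[str] = DEFAULT_STOPWORDS

    # -- construction ----------------------------------------------------

    def add_document(self, doc: Document) -> None:
        if doc.doc_id in self.doc_lengths:
            raise DuplicateDocumentError(f"duplicate doc_id: {doc.doc_id!r}")
        stream = tokenize(doc.text(self.section_mode), self.stopwords)
        self.doc_lengths[doc.doc_id] = len(stream)
        self.doc_count += 1
        for term in stream:
            self.postings.setdefault(term, {})
            self.postings[term][doc.doc_id] = self.postings[term].get(doc.doc_id, 0) + 1

    # -- statistics ------------------------------------------------------

    def document_frequency(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def idf(self, term: str) -> float:
        """ln(|D| / (df + 1)); add-one damping keeps absent terms finite."""
        return math.log(self.doc_count / (self.document_frequency(term) + 1))

    # -- retrieval -------------------------------------------------------

    def retrieve(self, query_text: str, n: int) -> list[tuple[str, float]]:
        """Top-``n`` documents matching any query token, best first.

        Returns ``(doc_id, score)`` pairs sorted by descending score, ties
        by ascending doc_id; fewer than ``n`` results only when fewer
        candidates exist. An all-stopword or empty query yields ``[]``.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        terms = sorted(set(tokenize(query_text, self.stopwords)))
        scores: dict[str, float] = {}
        for term in terms:
            posting = self.postings.get(term)
            if not posting:
                continue
            w = self.idf(term)
            for doc_id, tf in posting.items():
                scores[doc_id] = scores.get(doc_id, 0.0) + tf * w
        ranked = sorted(
            ((doc_id, s / math.sqrt(self.doc_lengths[doc_id])) for doc_id, s in scores.items()),
            key=lambda item: (-item[1], item[0]),
        )
        return ranked[:n]

    # -- persistence -----------------------------------------------------

    def save(self, dirpath: str | Path) -> None:
        """Write the index as sorted plain-text files (reproducibly)."""
        d = Path(dirpath)
        d.mkdir(parents=True, exist_ok=True)
        meta = {"doc_count": self.doc_count, "section_mode": self.section_mode}
        (d / "index_meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")
        with open(d / "postings.tsv", "w", encoding="utf-8") as fh:
            for term in sorted(self.postings):
                cells = " ".join(
                    f"{doc_id}:{tf}" for doc_id, tf in sorted(self.postings[term].items())
                )
                fh.write(f"{term}\t{cells}\n")
        with open(d / "doc_lengths.tsv", "w", encoding="utf-8") as fh:
            for doc_id in sorted(self.doc_lengths):
                fh.write(f"{doc_id}\t{self.doc_lengths[doc_id]}\n")
        with open(d / "stopwords.txt", "w", encoding="utf-8") as fh:
            for term in sorted(self.stopwords):
                fh.write(term + "\n")

    @classmethod
    def load(cls, dirpath: str | Path) -> "CorpusIndex":
        d = Path(dirpath)
        meta = json.loads((d / "index_meta.json").read_text())
        stopwords = frozenset(
            line.strip()
            for line in (d / "stopwords.txt").read_text(encoding="utf-8").splitlines()
            if line.strip()
        )
        idx = cls(
            doc_count=meta["doc_count"],
            section_mode=meta["section_mode"],
            stopwords=stopwords,
        )
        with open(d / "postings.tsv", encoding="utf-8") as fh:
            for line in fh:
                term, cells = line.rstrip("\n").split("\t")
                posting = {}
                for cell in cells.split(" "):
                    doc_id, tf = cell.rsplit(":", 1)
                    posting[doc_id] = int(tf)
                idx.postings[term] = posting
        with open(d / "doc_lengths.tsv", encoding="utf-8") as fh:
            for line in fh:
                doc_id, length = line.rstrip("\n").split("\t")
                idx.doc_lengths[doc_id] = int(length)
        return idx


def build_index(
    documents: Iterable[Document],
    section_mode: str = "full",
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> CorpusIndex:
    """Ingest a document stream into a fresh :class:`CorpusIndex`."""
    index = CorpusIndex(section_mode=section_mode, stopwords=stopwords)
    for doc in documents:
        index.add_document(doc)
    return index
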