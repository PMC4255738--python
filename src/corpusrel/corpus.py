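"""Corpus input: documents, tokenization and stopword handling.

A corpus is any iterable of :class:`Document`. Two on-disk layouts are
supported: a directory of UTF-8 ``.txt`` files (the filename stem is the
document id and the file content is the body), and a JSON-lines file with
one record per line carrying ``doc_id``, ``title``, ``abstract`` and
``body`` fields.

Tokenization mirrors the behavior of a standard analyzer: maximal
alphanumeric runs, lowercased, with stopwords removed. The default
stopword set is the classic 33-word English list used by Lucene's
StandardAnalyzer; callers may substitute any other set.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Tuple

__all__ = [
    "DEFAULT_STOPWORDS",
    "Document",
    "TokenStream",
    "tokenize",
    "read_corpus_dir",
    "read_corpus_jsonl",
    "load_corpus",
    "load_stopwords",
]

#: The 33 English stopwords of Lucene's StandardAnalyzer.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be but by for if in into is it no not of on or
    such that the their then there these they this to was will with""".split()
)

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")

SECTION_MODES = ("full", "abstract_only")


@dataclass(frozen=True)
class Document:
    """One corpus record; the unit of preprocessing.

    ``title``/``abstract``/``body`` may each be empty; an indexable
    document has at least one non-empty section.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    body: str = ""

    def text(self, section_mode: str = "full") -> str:
        """Concatenate the sections selected by ``section_mode``.

        ``full`` uses title + abstract + body; ``abstract_only`` models a
        compact corpus of titles and abstracts.
        """
        if section_mode not in SECTION_MODES:
            raise ValueError(f"unknown section_mode: {section_mode!r}")
        parts = [self.title, self.abstract]
        if section_mode == "full":
            parts.append(self.body)
        return "\n".join(p for p in parts if p)


@dataclass
class TokenStream:
    """Ordered normalized terms with their original character offsets."""

    terms: list[str] = field(default_factory=list)
    offsets: list[Tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)


def tokenize(text: str, stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS) -> TokenStream:
    """Split ``text`` into lowercase alphanumeric tokens, dropping stopwords.

    Any non-alphanumeric character is a token boundary (so hyphens split:
    ``"Bardet-Biedl"`` -> ``bardet``, ``biedl``). Deterministic; empty
    input yields an empty stream.
    """
    stream = TokenStream()
    for m in _TOKEN_RE.finditer(text):
        term = m.group(0).lower()
        if term in stopwords:
            continue
        stream.terms.append(term)
        stream.offsets.append((m.start(), m.end()))
    return stream


def read_corpus_dir(path: str | Path) -> Iterator[Document]:
    """Yield documents from a directory of ``.txt`` files, sorted by name."""
    root = Path(path)
    for fp in sorted(root.glob("*.txt")):
        yield Document(doc_id=fp.stem, body=fp.read_text(encoding="utf-8"))


def read_corpus_jsonl(path: str | Path) -> Iterator[Document]:
    """Yield documents from a one-JSON-record-per-line file."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            yield Document(
                doc_id=str(rec["doc_id"]),
                title=rec.get("title", "") or "",
                abstract=rec.get("abstract", "") or "",
                body=rec.get("body", "") or "",
            )


def load_corpus(path: str | Path) -> Iterator[Document]:
    """Auto-detect the corpus layout: directory of .txt or a JSONL file."""
    p = Path(path)
    if p.is_dir():
        return read_corpus_dir(p)
    return read_corpus_jsonl(p)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword override file: one lowercase term per line."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            term = line.strip().lower()
            if term:
                terms.append(term)
    return frozenset(terms)
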