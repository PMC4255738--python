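"""Runtime relatedness scoring.

For each input label the index returns its top-N matching documents, the
stored vectors of those documents are summed into one aggregate context
vector, and the relatedness of two labels is the cosine of their
aggregates:

    r(s, t) = cos( sum V(D(s)), sum V(D(t)) )

Because stored weights are strictly positive, cosine lies in [0, 1]. A
label for which no document (or only vector-less documents) can be
retrieved gets a zero aggregate; any pair involving such a label scores
exactly 0 — the null interpretation that a concept absent from the corpus
is most likely unrelated to the concepts present in it.

Defaults (N = 20 aggregated documents, plain variant DB at c = 0.05)
follow the configuration used for the large-scale rare-disease
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .index import CorpusIndex
from .vectorizer import SparseVector, VectorDB

__all__ = [
    "RelatednessConfig",
    "RelatednessResult",
    "aggregate_vector",
    "cosine",
    "score_pair",
]

DEFAULT_N_DOCS = 20


@dataclass
class RelatednessConfig:
    """Runtime configuration: a corpus index, its vector DB, and N."""

    index: CorpusIndex
    vector_db: VectorDB
    n_docs: int = DEFAULT_N_DOCS

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")


@dataclass
class RelatednessResult:
    label1: str
    label2: str
    score: float
    covered1: bool
    covered2: bool
    n_docs_used1: int
    n_docs_used2: int


def _aggregate(label: str, config: RelatednessConfig) -> tuple[SparseVector, int]:
    hits = config.index.retrieve(label, config.n_docs)
    entries: dict[int, float] = {}
    for doc_id, _score in hits:
        vec = config.vector_db.vectors.get(doc_id)
        if vec is None:
            continue  # a doc whose trimmed bag was empty contributes nothing
        for idx, value in vec.entries.items():
            entries[idx] = entries.get(idx, 0.0) + value
    dim = len(config.vector_db.vocab)
    return SparseVector(entries=entries, dimensionality=dim), len(hits)


def aggregate_vector(label: str, config: RelatednessConfig) -> SparseVector:
    """Sum of the stored vectors of the label's top-N retrieved documents."""
    vec, _ = _aggregate(label, config)
    return vec


def cosine(v1: SparseVector, v2: SparseVector) -> float:
    """Cosine similarity; 0 when either vector is zero; clipped to [0, 1]."""
    if v1.is_zero() or v2.is_zero():
        return 0.0
    if len(v2.entries) < len(v1.entries):
        v1, v2 = v2, v1
    dot = 0.0
    # accumulate in sorted dimension order: the sum is then independent of
    # argument order and insertion history, making scores exactly symmetric
    for idx in sorted(v1.entries):
        other = v2.entries.get(idx)
        if other is not None:
            dot += v1.entries[idx] * other
    if dot == 0.0:
        return 0.0
    return min(1.0, dot / (v1.norm() * v2.norm()))


def score_pair(label1: str, label2: str, config: RelatednessConfig) -> RelatednessResult:
    """Full STEP 1-4 pipeline for one label pair; symmetric in its inputs."""
    v1, used1 = _aggregate(label1, config)
    v2, used2 = _aggregate(label2, config)
    return RelatednessResult(
        label1=label1,
        label2=label2,
        score=cosine(v1, v2),
        covered1=not v1.is_zero(),
        covered2=not v2.is_zero(),
        n_docs_used1=used1,
        n_docs_used2=used2,
    )
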