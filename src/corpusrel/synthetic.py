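"""Seed-controlled synthetic corpora with planted topical structure.

The generator emulates the one property of a scientific corpus that a
distributional relatedness measure actually exploits: documents about the
same topic share topic-specific vocabulary against a common background.
Each document belongs to one topic; its tokens are drawn i.i.d. — with
probability ``topic_token_fraction`` uniformly from the topic's private
vocabulary, otherwise from a shared Zipf-distributed background
vocabulary. A closed list of pseudo-preposition tokens is interleaved at
a fixed rate (one slot every ``preposition_interval`` tokens) so that
prepositional key-phrase grammars have something to fire on.

Gold benchmarks are planted from topic co-membership: pairs of topic
terms from the same topic get gold relatedness 1, pairs straddling two
topics get 0. Recovering this signal end-to-end (index, vectorize,
retrieve, aggregate, cosine) is the package's principal self-test.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus import Document
from .tgsp import PREPOSITIONS

__all__ = ["SyntheticSpec", "PlantedGold", "generate_corpus", "generate_gold", "write_gold_tsv"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-topic corpus.

    Defaults are the package's canonical self-test conditions: 5 topics of
    40 documents, 30 topic terms each over a 500-term Zipf(1.1)
    background, half of each 150-token document drawn from its topic.
    """

    n_topics: int = 5
    docs_per_topic: int = 40
    topic_vocab_size: int = 30
    background_vocab_size: int = 500
    topic_token_fraction: float = 0.5
    doc_length: int = 150
    zipf_exponent: float = 1.1
    seed: int = 7
    preposition_interval: int = 10  # 0 disables preposition slots

    def __post_init__(self) -> None:
        for name in ("n_topics", "docs_per_topic", "topic_vocab_size",
                     "background_vocab_size", "doc_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.topic_token_fraction <= 1:
            raise ValueError("topic_token_fraction must be in (0, 1]")
        if self.preposition_interval < 0:
            raise ValueError("preposition_interval must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class PlantedGold:
    """(term1, term2, gold) pairs; gold 1 = same topic, 0 = cross topic."""

    pairs: list[tuple[str, str, float]]


def topic_terms(spec: SyntheticSpec, topic: int) -> list[str]:
    return [f"t{topic}w{j}" for j in range(spec.topic_vocab_size)]


def background_terms(spec: SyntheticSpec) -> list[str]:
    return [f"bg{k}" for k in range(spec.background_vocab_size)]


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    weights = 1.0 / np.arange(1, size + 1, dtype=float) ** exponent
    return weights / weights.sum()


def generate_corpus(spec: SyntheticSpec) -> list[Document]:
    """Deterministically sample the corpus; every topic term is guaranteed
    to occur in at least one document of its topic (topics are resampled
    until that holds)."""
    if spec.topic_vocab_size > spec.doc_length * spec.docs_per_topic:
        raise ValueError("infeasible spec: topic vocabulary larger than topic token budget")
    rng = np.random.default_rng(spec.seed)
    bg = background_terms(spec)
    bg_probs = _zipf_probs(spec.background_vocab_size, spec.zipf_exponent)
    docs: list[Document] = []
    for topic in range(spec.n_topics):
        terms = topic_terms(spec, topic)
        for _attempt in range(100):
            topic_docs: list[Document] = []
            used: set[str] = set()
            for d in range(spec.docs_per_topic):
                tokens: list[str] = []
                for pos in range(spec.doc_length):
                    if (
                        spec.preposition_interval
                        and (pos + 1) % spec.preposition_interval == 0
                    ):
                        tokens.append(PREPOSITIONS[rng.integers(len(PREPOSITIONS))])
                    elif rng.random() < spec.topic_token_fraction:
                        term = terms[rng.integers(len(terms))]
                        used.add(term)
                        tokens.append(term)
                    else:
                        tokens.append(bg[rng.choice(len(bg), p=bg_probs)])
                topic_docs.append(Document(doc_id=f"t{topic}d{d:03d}", body=" ".join(tokens)))
            if used.issuperset(terms):
                docs.extend(topic_docs)
                break
        else:
            raise ValueError("failed to cover the topic vocabulary in 100 resamples")
    return docs


def generate_gold(spec: SyntheticSpec, n_pos: int = 25, n_neg: int = 25) -> PlantedGold:
    """Sample unique same-topic (gold 1) and cross-topic (gold 0) term pairs."""
    max_pos = spec.n_topics * spec.topic_vocab_size * (spec.topic_vocab_size - 1) // 2
    n_cross = spec.n_topics * (spec.n_topics - 1) // 2
    max_neg = n_cross * spec.topic_vocab_size * spec.topic_vocab_size
    if n_pos > max_pos or n_neg > max_neg:
        raise ValueError("insufficient topic vocabulary for the requested pair counts")
    rng = np.random.default_rng([spec.seed, 104729])
    pairs: list[tuple[str, str, float]] = []
    seen: set[frozenset[str]] = set()
    while sum(1 for p in pairs if p[2] == 1.0) < n_pos:
        topic = int(rng.integers(spec.n_topics))
        i, j = rng.choice(spec.topic_vocab_size, size=2, replace=False)
        a, b = f"t{topic}w{i}", f"t{topic}w{j}"
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            pairs.append((a, b, 1.0))
    while sum(1 for p in pairs if p[2] == 0.0) < n_neg:
        t1, t2 = rng.choice(spec.n_topics, size=2, replace=False)
        a = f"t{t1}w{int(rng.integers(spec.topic_vocab_size))}"
        b = f"t{t2}w{int(rng.integers(spec.topic_vocab_size))}"
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            pairs.append((a, b, 0.0))
    return PlantedGold(pairs=pairs)


def write_gold_tsv(gold: PlantedGold, path: str | Path) -> None:
    """Write planted pairs in the benchmark TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label1\tlabel2\tgold\n")
        for a, b, score in gold.pairs:
            fh.write(f"{a}\t{b}\t{score}\n")
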