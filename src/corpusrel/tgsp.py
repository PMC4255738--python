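"""T-GSP frequent key-phrase extraction.

T-GSP (Text General Sequential Pattern) mines the frequent terms and
collocations of a single document in one pass of a sliding window,
keeping only candidates whose coarse part-of-speech sequence matches one
of a small set of grammar patterns (e.g. ``[noun]``, ``[noun, noun]``,
``[noun, preposition, noun]``). The output is a table of candidate
key-phrases sorted by descending in-document frequency, which is then cut
down by a cumulative-frequency trimming rule: phrases are included in
sorted order until their frequency mass exceeds a threshold fraction ``c``
of the total, and inclusion then continues through every phrase tied with
the last one admitted.

The tagger is a pluggable contract: any callable mapping a term to one of
the five coarse tags. :class:`LookupTagger` implements the knowledge-poor
default used throughout this package — a closed list of prepositions,
everything else a noun — which keeps extraction deterministic and free of
external models.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .corpus import TokenStream

__all__ = [
    "COARSE_TAGS",
    "DEFAULT_GRAMMARS",
    "PREPOSITIONS",
    "PosToken",
    "PhraseCandidate",
    "PhraseTable",
    "LookupTagger",
    "default_tagger",
    "pos_tag",
    "extract_candidates",
    "trim_phrase_table",
    "load_grammars",
]

COARSE_TAGS = ("noun", "preposition", "adjective", "verb", "other")

#: Grammar patterns accepted by default: single nouns, noun compounds up
#: to length three, and prepositional noun collocations.
DEFAULT_GRAMMARS: tuple[tuple[str, ...], ...] = (
    ("noun",),
    ("noun", "noun"),
    ("noun", "preposition", "noun"),
    ("noun", "noun", "noun"),
)

#: Closed preposition list for the default tagger; deliberately disjoint
#: from the default stopword set so prepositional grammars can fire after
#: stopword removal.
PREPOSITIONS = (
    "via", "versus", "amid", "atop", "onto",
    "toward", "beneath", "beyond", "despite", "along",
)

DEFAULT_WINDOW = 4


@dataclass(frozen=True)
class PosToken:
    term: str
    pos: str

    def __post_init__(self) -> None:
        if self.pos not in COARSE_TAGS:
            raise ValueError(f"unknown coarse tag: {self.pos!r}")


@dataclass(frozen=True)
class PhraseCandidate:
    """A candidate key-phrase with its in-document occurrence count."""

    phrase: tuple[str, ...]
    frequency: int


@dataclass
class PhraseTable:
    """Candidates of one document, sorted by descending frequency.

    Ties are ordered by first occurrence position, then lexicographically;
    the trimming rule is insensitive to tie order because it always keeps
    or drops a tie group whole.
    """

    candidates: list[PhraseCandidate]
    total_frequency: int


class LookupTagger:
    """Coarse tagger backed by a term -> tag table with a default tag."""

    def __init__(self, table: dict[str, str] | None = None, default: str = "noun"):
        if default not in COARSE_TAGS:
            raise ValueError(f"unknown coarse tag: {default!r}")
        self.table = dict(table or {})
        self.default = default

    def __call__(self, term: str) -> str:
        return self.table.get(term, self.default)


def default_tagger() -> LookupTagger:
    """Prepositions from the closed list; every other term a noun."""
    return LookupTagger({p: "preposition" for p in PREPOSITIONS})


def pos_tag(tokens: TokenStream | Iterable[str], tagger: Callable[[str], str]) -> list[PosToken]:
    """Tag every token; a failing or out-of-set tagger answer becomes "other"."""
    tagged = []
    for term in tokens:
        try:
            tag = tagger(term)
        except Exception:
            tag = "other"
        if tag not in COARSE_TAGS:
            tag = "other"
        tagged.append(PosToken(term, tag))
    return tagged


def extract_candidates(
    tagged: Sequence[PosToken],
    grammars: Iterable[tuple[str, ...]] = DEFAULT_GRAMMARS,
    window: int = DEFAULT_WINDOW,
) -> PhraseTable:
    """Count grammar-matching contiguous runs at every window position.

    At each starting position, each grammar whose tag sequence exactly
    matches the contiguous run beginning there contributes one count to
    that run's phrase. Counts are aggregated document-wide.
    """
    grammar_set = [tuple(g) for g in grammars]
    for g in grammar_set:
        if not g:
            raise ValueError("empty grammar pattern")
        if len(g) > window:
            raise ValueError(f"window {window} shorter than grammar {g}")
    counts: Counter[tuple[str, ...]] = Counter()
    first_seen: dict[tuple[str, ...], int] = {}
    tags = [t.pos for t in tagged]
    terms = [t.term for t in tagged]
    n = len(tagged)
    for i in range(n):
        for g in grammar_set:
            j = i + len(g)
            if j <= n and tags[i:j] == list(g):
                phrase = tuple(terms[i:j])
                counts[phrase] += 1
                first_seen.setdefault(phrase, i)
    candidates = [
        PhraseCandidate(phrase, freq)
        for phrase, freq in sorted(
            counts.items(), key=lambda kv: (-kv[1], first_seen[kv[0]], kv[0])
        )
    ]
    return PhraseTable(candidates=candidates, total_frequency=sum(counts.values()))


def trim_phrase_table(table: PhraseTable, c: float) -> list[PhraseCandidate]:
    """Keep the frequency-sorted prefix whose mass first exceeds ``c`` of
    the total, extended through all candidates tied with the last one kept.

    If the cumulative mass never strictly exceeds ``c * total`` (e.g.
    ``c = 1``), every candidate is kept.
    """
    if not 0 < c <= 1:
        raise ValueError(f"trimming threshold must be in (0, 1], got {c}")
    if not table.candidates:
        return []
    threshold = c * table.total_frequency
    cumulative = 0
    crossing = None
    for i, cand in enumerate(table.candidates):
        cumulative += cand.frequency
        if cumulative > threshold:
            crossing = i
            break
    if crossing is None:
        return list(table.candidates)
    kept = list(table.candidates[: crossing + 1])
    pivot = table.candidates[crossing].frequency
    for cand in table.candidates[crossing + 1 :]:
        if cand.frequency != pivot:
            break
        kept.append(cand)
    return kept


def load_grammars(path: str | Path) -> tuple[tuple[str, ...], ...]:
    """Read grammar patterns from text config: one comma-separated tag
    sequence per line; blank lines and ``#`` comments ignored."""
    patterns = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        pattern = tuple(tag.strip() for tag in line.split(","))
        for tag in pattern:
            if tag not in COARSE_TAGS:
                raise ValueError(f"unknown coarse tag in grammar config: {tag!r}")
        patterns.append(pattern)
    return tuple(patterns)
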