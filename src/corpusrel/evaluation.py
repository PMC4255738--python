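"""Evaluation machinery: tied-rank correlation, coverage, benchmarks.

Quality against human judgement is measured by Spearman's rank
correlation with average ranks assigned to ties — the Pearson formula
applied to rank-transformed scores:

    rho(X, Y) = sum_i (x_i - mean x)(y_i - mean y)
                / sqrt( sum (x_i - mean x)^2 * sum (y_i - mean y)^2 )

Coverage quantifies how often the method produces a usable (non-zero)
context vector: r_s is the covered fraction of single inputs, r_p the
fraction of pairs whose both vectors are non-zero. Pairs that are not
covered are still scored (as 0) and kept in the correlation — the null
policy pushes the score distribution toward the bottom as coverage drops,
rather than silently shrinking the sample.

Large-scale experiments enumerate exhaustive label-pair sets: all cross
pairs of two deduplicated lists, or all unordered pairs within one list.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .relatedness import RelatednessConfig, aggregate_vector, cosine
from .vectorizer import SparseVector

__all__ = [
    "DegenerateDataError",
    "BenchmarkPair",
    "EvaluationReport",
    "PairStream",
    "rank_with_ties",
    "spearman",
    "pearson",
    "coverage_single",
    "coverage_pairs",
    "dedupe_labels",
    "enumerate_cross_pairs",
    "enumerate_unordered_pairs",
    "read_benchmark_tsv",
    "run_benchmark",
]


class DegenerateDataError(ValueError):
    """Raised when a correlation is undefined (zero rank variance)."""


def rank_with_ties(values: Sequence[float]) -> list[float]:
    """Ranks 1..n; tied values share the mean of the ranks they span."""
    if len(values) == 0:
        raise ValueError("cannot rank an empty list")
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def _pearson(x: Sequence[float], y: Sequence[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        raise DegenerateDataError("zero variance; correlation undefined")
    return sxy / math.sqrt(sxx * syy)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation with average tied ranks (primary quality metric)."""
    if len(x) != len(y):
        raise ValueError("input lists differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return _pearson(rank_with_ties(x), rank_with_ties(y))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Raw-score Pearson correlation (secondary, behind a flag in the CLI)."""
    if len(x) != len(y):
        raise ValueError("input lists differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return _pearson(x, y)


def coverage_single(vectors: Sequence[SparseVector]) -> float:
    """r_s: fraction of inputs whose aggregate vector is non-zero."""
    if not vectors:
        raise ValueError("empty input set")
    zero = sum(1 for v in vectors if v.is_zero())
    return (len(vectors) - zero) / len(vectors)  # exact rational over |S|


def coverage_pairs(pairs: Sequence[tuple[SparseVector, SparseVector]]) -> float:
    """r_p: fraction of pairs where both aggregate vectors are non-zero."""
    if not pairs:
        raise ValueError("empty pair set")
    bad = sum(1 for v1, v2 in pairs if v1.is_zero() or v2.is_zero())
    return (len(pairs) - bad) / len(pairs)


def dedupe_labels(labels: Iterable[str]) -> list[str]:
    """Whitespace-normalize and deduplicate, preserving first occurrence."""
    seen: set[str] = set()
    out: list[str] = []
    for label in labels:
        norm = " ".join(label.split())
        if norm and norm not in seen:
            seen.add(norm)
            out.append(norm)
    return out


@dataclass
class PairStream:
    """A lazily enumerated pair set with its closed-form count."""

    count: int
    pairs: Iterator[tuple[str, str]]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return self.pairs


def enumerate_cross_pairs(list_a: Iterable[str], list_b: Iterable[str]) -> PairStream:
    """All |A| x |B| ordered pairs of two deduplicated label lists."""
    a = dedupe_labels(list_a)
    b = dedupe_labels(list_b)

    def gen() -> Iterator[tuple[str, str]]:
        for x in a:
            for y in b:
                yield (x, y)

    return PairStream(count=len(a) * len(b), pairs=gen())


def enumerate_unordered_pairs(list_a: Iterable[str]) -> PairStream:
    """All n(n-1)/2 unordered pairs within one deduplicated list."""
    a = dedupe_labels(list_a)
    n = len(a)

    def gen() -> Iterator[tuple[str, str]]:
        for i in range(n):
            for j in range(i + 1, n):
                yield (a[i], a[j])

    return PairStream(count=n * (n - 1) // 2, pairs=gen())


@dataclass
class BenchmarkPair:
    label1: str
    label2: str
    gold: float | None = None
    predicted: float | None = None
    covered: bool | None = None


@dataclass
class EvaluationReport:
    rho: float | None
    r_s: float
    r_p: float
    n_pairs: int
    n_skipped_rows: int
    config: dict = field(default_factory=dict)


def read_benchmark_tsv(path: str | Path) -> tuple[list[BenchmarkPair], int]:
    """Parse a (label1, label2[, gold]) TSV with a required header.

    Malformed rows (wrong arity, unparsable gold) are skipped and counted.
    """
    pairs: list[BenchmarkPair] = []
    skipped = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"empty benchmark file: {path}")
        if len(header) < 2 or header[0].strip().lower() != "label1":
            raise ValueError(f"missing label1/label2 header in {path}")
        has_gold = len(header) >= 3
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                skipped += 1
                continue
            gold: float | None = None
            if has_gold and len(row) >= 3 and row[2].strip():
                try:
                    gold = float(row[2])
                except ValueError:
                    skipped += 1
                    continue
            pairs.append(BenchmarkPair(label1=row[0].strip(), label2=row[1].strip(), gold=gold))
    if not pairs:
        raise ValueError(f"no valid rows in benchmark file: {path}")
    return pairs, skipped


def run_benchmark(
    pairs_file: str | Path,
    config: RelatednessConfig,
    correlation: str = "spearman",
) -> tuple[EvaluationReport, list[BenchmarkPair]]:
    """Score every benchmark pair and summarize quality and coverage.

    Aggregate vectors are computed once per distinct label. rho is
    reported only when every pair carries a gold score; uncovered pairs
    enter the correlation with their (zero) predicted score.
    """
    if correlation not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation: {correlation!r}")
    pairs, skipped = read_benchmark_tsv(pairs_file)
    labels = dedupe_labels([p.label1 for p in pairs] + [p.label2 for p in pairs])
    agg = {label: aggregate_vector(label, config) for label in labels}

    def vec(label: str) -> SparseVector:
        return agg[" ".join(label.split())]

    for p in pairs:
        v1, v2 = vec(p.label1), vec(p.label2)
        p.predicted = cosine(v1, v2)
        p.covered = not (v1.is_zero() or v2.is_zero())

    r_s = coverage_single(list(agg.values()))
    r_p = coverage_pairs([(vec(p.label1), vec(p.label2)) for p in pairs])
    rho = None
    if all(p.gold is not None for p in pairs):
        corr = spearman if correlation == "spearman" else pearson
        rho = corr([p.gold for p in pairs], [p.predicted for p in pairs])
    report = EvaluationReport(
        rho=rho,
        r_s=r_s,
        r_p=r_p,
        n_pairs=len(pairs),
        n_skipped_rows=skipped,
        config={
            "n_docs": config.n_docs,
            "variant": config.vector_db.config.variant,
            "c": config.vector_db.config.c,
            "correlation": correlation,
        },
    )
    return report, pairs
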