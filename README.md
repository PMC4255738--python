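# corpusrel

Knowledge-poor, corpus-based approximation of **semantic relatedness**
between free-text labels, aimed at biomedical text mining: given two
labels such as a gene name and a disorder name, the method estimates how
strongly they are associated using nothing but a document corpus — no
ontology, thesaurus or curated knowledge base.

## The method

The core assumption is distributional: the most relevant documents for
related concepts contain similar vocabulary. The pipeline:

1. **Preprocessing (offline, per document).** Each corpus document *d* is
   reduced to a sparse vector of positive tf-idf weights,

       tfidf(t, d, D) = tf(t, d) · idf(t, D),
       idf(t, D) = ln( |D| / (|{d ∈ D : t ∈ d}| + 1) ),

   under one of two variants:
   * **plain** — the document's own bag of words is weighted, and each
     vector is trimmed to its top-weight fraction *c* of stored
     dimensions;
   * **tgsp** — T-GSP key-phrase mining (single-pass sliding window over
     POS-tagged tokens, filtered by grammars such as `[noun]`,
     `[noun, noun]`, `[noun, preposition, noun]`) produces a frequency
     table per document, which is trimmed at cumulative-frequency
     threshold *c* and tokenized into the bag of words. Nothing
     cross-document is used before the idf pass, so the stage is
     embarrassingly parallel.

   Vectors are stored positive-only in a plain-text vector database.
2. **Retrieval (online).** An input label is parsed as an OR query over
   its tokens (the least restrictive boolean reading) against an inverted
   index; the top *N* documents are retrieved.
3. **Aggregation.** The stored vectors of those *N* documents are summed
   into one context vector per label.
4. **Scoring.** Relatedness is the cosine of the two context vectors,
   r(s, t) ∈ [0, 1]. A label with no retrievable context scores 0 against
   everything (the null interpretation: absent from the corpus ≈
   unrelated to what is in it).

Evaluation utilities compute Spearman's ρ with average tied ranks against
gold human ratings, single-input coverage r_s and pair coverage r_p, and
exhaustive pair-set enumeration for large-scale screening experiments.
A seed-controlled synthetic corpus generator (topic-private vocabularies
over a Zipfian background) provides planted-gold benchmarks so the whole
pipeline is testable offline.

## Worked example

```python
from corpusrel import (BuildConfig, RelatednessConfig, SyntheticSpec,
                       build_index, build_vector_db, generate_corpus, score_pair)

spec = SyntheticSpec(n_topics=2, docs_per_topic=15, topic_vocab_size=10,
                     background_vocab_size=100, doc_length=80, seed=11)
docs = generate_corpus(spec)
config = RelatednessConfig(
    index=build_index(docs),
    vector_db=build_vector_db(docs, BuildConfig(variant="plain", c=0.2)),
    n_docs=5,
)
for a, b in [("t0w0", "t0w1"), ("t0w0", "t1w0"), ("t0w0", "notinthecorpus")]:
    r = score_pair(a, b, config)
    print(f"r({a!r}, {b!r}) = {r.score:.3f}  covered=({r.covered1}, {r.covered2})")
```

prints

```
r('t0w0', 't0w1') = 0.570  covered=(True, True)
r('t0w0', 't1w0') = 0.006  covered=(True, True)
r('t0w0', 'notinthecorpus') = 0.000  covered=(True, False)
```

Two labels from the same planted topic share retrieved-document
vocabulary and score 0.570; labels from different topics overlap only in
background vocabulary (0.006); a label absent from the corpus is
uncovered and scores exactly 0. More narrative scripts live in
`examples/` (key-phrase mining, a full benchmark run, pair enumeration),
and a thin CLI mirrors the library:

```bash
corpusrel synth corpus --out corpus.jsonl
corpusrel index --corpus corpus.jsonl --out idx/
corpusrel vectorize --corpus corpus.jsonl --variant plain --cutoff 0.2 --out db/
corpusrel score --indexdir idx/ --db db/ --n 10 "t0w0" "t0w1"
```

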