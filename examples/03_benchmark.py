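"""Run a gold benchmark on the canonical synthetic corpus.

Generates the planted-topic corpus and a 50-pair gold standard (same-topic
pairs are related, cross-topic pairs are not), scores every pair, and
reports the tied-rank correlation with gold plus single and pair coverage.
"""

import tempfile
from pathlib import Path

from corpusrel import (
    BuildConfig,
    RelatednessConfig,
    SyntheticSpec,
    build_index,
    build_vector_db,
    generate_corpus,
    generate_gold,
    run_benchmark,
)
from corpusrel.synthetic import write_gold_tsv

spec = SyntheticSpec()  # 5 topics x 40 docs, seed 7
docs = generate_corpus(spec)
index = build_index(docs)
db = build_vector_db(docs, BuildConfig(variant="plain", c=0.2))
config = RelatednessConfig(index=index, vector_db=db, n_docs=10)

with tempfile.TemporaryDirectory() as tmp:
    gold_path = Path(tmp) / "gold.tsv"
    write_gold_tsv(generate_gold(spec, n_pos=25, n_neg=25), gold_path)
    report, pairs = run_benchmark(gold_path, config)

print(f"pairs scored          : {report.n_pairs}")
print(f"Spearman rho vs gold  : {report.rho:.3f}")
print(f"single coverage r_s   : {report.r_s:.3f}")
print(f"pair coverage r_p     : {report.r_p:.3f}")
print("\nrho near the binary-gold ceiling (~0.87) means the method ranks")
print("nearly every same-topic pair above every cross-topic pair; full")
print("coverage means every label produced a non-zero context vector.")
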