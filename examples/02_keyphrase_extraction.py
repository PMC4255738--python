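"""Mine frequent key-phrases from one document with T-GSP.

A sliding window counts contiguous token runs whose coarse POS sequence
matches a grammar ([noun], [noun, noun], [noun, preposition, noun], ...);
the frequency-sorted table is then trimmed to the candidates holding the
top share of the total frequency mass.
"""

from corpusrel import LookupTagger, extract_candidates, pos_tag, tokenize, trim_phrase_table

text = (
    "Cancer patient received cancer treatment. Treatment versus surgery: "
    "the cancer patient chose treatment, and the patient recovered."
)
tagger = LookupTagger({"versus": "preposition"}, default="noun")
tokens = tokenize(text)
table = extract_candidates(pos_tag(tokens, tagger))

print("candidate key-phrases (phrase: in-document frequency):")
for cand in table.candidates:
    print(f"  {' '.join(cand.phrase):30s} {cand.frequency}")

kept = trim_phrase_table(table, c=0.3)
print(f"\nkept after trimming at c=0.3 (top 30% of frequency mass, plus ties):")
for cand in kept:
    print(f"  {' '.join(cand.phrase):30s} {cand.frequency}")
print("\nThese kept phrases form the document's bag of words in the tgsp variant.")
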