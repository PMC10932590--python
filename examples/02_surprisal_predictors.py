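"""Build frequency and predictability predictors on the surprisal scale.

Counts n-grams from a toy corpus, computes unigram (frequency) and
Kneser-Ney bigram surprisal in nats, and recovers word-level surprisal
from precomputed subtoken log-probabilities by the chain rule.
"""

import numpy as np

from ctdreg.predictors import (
    count_ngrams,
    ngram_surprisal,
    tokenize,
    unigram_surprisal,
    word_surprisal_from_subtokens,
)

corpus = [
    tokenize("The cat sat on the mat."),
    tokenize("The dog sat on the rug."),
    tokenize("A cat and a dog met on the mat."),
]
counts = count_ngrams(corpus, max_order=2)

print(f"corpus: {counts.total} tokens, {len(counts.vocab)} types")
for w in ("the", "cat", "rug", "platypus"):
    print(f"  unigram surprisal({w!r:12}) = {unigram_surprisal(counts, w):5.2f} nats")
print("rarer words get higher surprisal; unseen words fall back to <unk>")

print("\nKneser-Ney bigram surprisal (discount 0.75):")
for ctx, w in [(("the",), "cat"), (("the",), "rug"), (("sat",), "on")]:
    s = ngram_surprisal(counts, ctx, w, order=2)
    print(f"  -ln p({w!r} | {ctx[0]!r}) = {s:5.2f} nats")

# a neural language model's subtoken log-probabilities aggregate to one
# word surprisal by summing (chain rule) - 'cauldron' split into two parts:
parts = [("cau", -2.0), ("ldron", -1.5)]
print(f"\nchain rule: surprisal('cauldron') = {word_surprisal_from_subtokens(parts)} nats"
      f" = {-parts[0][1]} + {-parts[1][1]}")
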