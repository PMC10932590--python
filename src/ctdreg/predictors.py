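"""Frequency and predictability predictors on the surprisal scale.

Frequency is operationalized as unigram surprisal, -ln p(word), the
negated log prior probability of the word (equivalent to negated log
frequency up to an additive constant).  Contextual predictability comes in
two forms: bigram/trigram surprisal from corpus counts with interpolated
Kneser-Ney smoothing (fixed discount 0.75), and word-level surprisal from
precomputed per-subtoken log-probabilities of a neural language model,
recovered by the chain rule (summing subtoken surprisals within the word).
All surprisals are in nats.

The package never runs a language model; subtoken log-probabilities are
consumed from a user-supplied table.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BOS",
    "EOS",
    "UNK",
    "CorpusCounts",
    "SubtokenLogProbs",
    "tokenize",
    "count_ngrams",
    "unigram_surprisal",
    "ngram_surprisal",
    "word_surprisal_from_subtokens",
    "attach_predictors",
    "detach_predictors",
    "write_counts",
    "read_counts",
    "read_subtoken_logprobs",
]

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"
KN_DISCOUNT = 0.75

_PUNCT = re.compile(r"^[\W_]+|[\W_]+$", flags=re.UNICODE)


def tokenize(text: str, lowercase: bool = True):
    """Whitespace tokenization with edge punctuation stripped."""
    toks = []
    for raw in text.split():
        t = _PUNCT.sub("", raw)
        if t:
            toks.append(t.lower() if lowercase else t)
    return toks


@dataclass
class CorpusCounts:
    """N-gram counts for orders 1..max_order with sentence-boundary padding.

    Unigram counts cover real tokens only (total = corpus size); higher
    orders include BOS padding and one EOS per sentence.
    """

    max_order: int
    counts: dict = field(default_factory=dict)  # order -> {tuple: count}
    total: int = 0

    @property
    def vocab(self):
        return {w for (w,) in self.counts.get(1, {})}

    def count(self, ngram):
        ngram = tuple(ngram)
        return self.counts.get(len(ngram), {}).get(ngram, 0)


def _as_sentences(tokens):
    if len(tokens) == 0:
        raise ValueError("empty corpus")
    if isinstance(tokens[0], (list, tuple)):
        sents = [list(s) for s in tokens if len(s) > 0]
        if not sents:
            raise ValueError("empty corpus")
        return sents
    return [list(tokens)]


def count_ngrams(tokens, max_order: int) -> CorpusCounts:
    """Count n-grams of orders 1..max_order.

    ``tokens`` is a flat token sequence (one sentence) or a list of
    sentences.  Orders >= 2 pad each sentence with order-1 BOS symbols and
    a final EOS.
    """
    if not 1 <= int(max_order) <= 3:
        raise ValueError("max_order must be in 1..3")
    sents = _as_sentences(tokens)
    out = CorpusCounts(max_order=max_order)
    uni = Counter()
    for sent in sents:
        uni.update(sent)
    out.counts[1] = {(w,): c for w, c in uni.items()}
    out.total = sum(uni.values())
    for order in range(2, max_order + 1):
        c = Counter()
        for sent in sents:
            padded = [BOS] * (order - 1) + sent + [EOS]
            for i in range(len(padded) - order + 1):
                c[tuple(padded[i : i + order])] += 1
        out.counts[order] = dict(c)
    return out


def unigram_surprisal(counts: CorpusCounts, word: str) -> float:
    """-ln p(word) under the maximum-likelihood unigram distribution.

    Unseen words map to the unknown-word symbol, scored with one
    pseudo-count against total + 1.
    """
    c = counts.count((word,))
    if c > 0:
        return float(-np.log(c / counts.total))
    return float(-np.log(1.0 / (counts.total + 1)))


# ---------------------------------------------------------------------------
# interpolated Kneser-Ney


def _kn_vocab(counts):
    """Event space for conditional distributions: word types, EOS, UNK."""
    return counts.vocab | {EOS, UNK}


def _base_distribution(counts):
    """Proper unigram base for KN interpolation over vocab | {EOS, UNK}:
    word types by corpus count, EOS by sentence count, UNK by one
    pseudo-count."""
    # EOS mass: number of sentences, read off the bigram table when present.
    if 2 in counts.counts:
        n_eos = sum(c for ng, c in counts.counts[2].items() if ng[-1] == EOS)
    else:
        n_eos = 1
    denom = counts.total + n_eos + 1
    probs = {w: counts.count((w,)) / denom for w in counts.vocab}
    probs[EOS] = n_eos / denom
    probs[UNK] = 1.0 / denom
    return probs


def _continuation_counts(counts, order):
    """N1+(. w_2..w_k): number of distinct left-extensions of each
    (order)-gram, from the (order+1)-gram table."""
    table = counts.counts[order + 1]
    cont = Counter()
    for ng in table:
        cont[ng[1:]] += 1
    return cont


def _kn_conditional(counts, context, word, order, D=KN_DISCOUNT, _highest=True):
    """Interpolated Kneser-Ney conditional p(word | context) at the given
    order.  The highest order uses raw counts; lower orders use
    continuation counts; the recursion bottoms out at the proper unigram
    base distribution.  An unseen context falls through to the next-lower
    distribution (reducing toward the unigram estimate)."""
    if order == 1:
        base = _base_distribution(counts)
        return base.get(word, base[UNK])
    table = counts.counts[order] if _highest else _continuation_counts(counts, order)
    ctx_total = 0
    n_types = 0
    c_ngram = 0
    for ng, c in table.items():
        if ng[:-1] == context:
            ctx_total += c
            n_types += 1
            if ng[-1] == word:
                c_ngram = c
    lower = _kn_conditional(counts, context[1:], word, order - 1, D, _highest=False)
    if ctx_total == 0:
        return lower
    disc = max(c_ngram - D, 0.0) / ctx_total
    lam = D * n_types / ctx_total
    return disc + lam * lower


def ngram_surprisal(counts: CorpusCounts, context, word: str, order: int) -> float:
    """-ln p(word | context) under interpolated Kneser-Ney smoothing with
    fixed discount 0.75.  context supplies the most recent order-1 tokens
    (shorter contexts are BOS-padded); unseen words map to UNK."""
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    if counts.max_order < order:
        raise ValueError(f"counts were built only to order {counts.max_order}")
    context = tuple(context)
    if len(context) < order - 1:
        context = (BOS,) * (order - 1 - len(context)) + context
    context = context[-(order - 1):]
    vocab = _kn_vocab(counts)
    if word not in vocab:
        word = UNK
    p = _kn_conditional(counts, context, word, order)
    return float(-np.log(p))


def word_surprisal_from_subtokens(parts) -> float:
    """Word surprisal by the chain rule: the sum of subtoken surprisals.

    ``parts`` is a non-empty sequence of (subtoken, log-probability <= 0)
    pairs; any subtokenization of the same joint probability gives the
    same total.
    """
    parts = list(parts)
    if len(parts) == 0:
        raise ValueError("empty subtoken list")
    total = 0.0
    for sub, lp in parts:
        lp = float(lp)
        if not np.isfinite(lp):
            raise ValueError(f"non-finite log-probability for subtoken {sub!r}")
        if lp > 0:
            raise ValueError(f"log-probability must be <= 0 for subtoken {sub!r}")
        total += -lp
    return total


@dataclass(frozen=True)
class SubtokenLogProbs:
    """Ordered (subtoken, log-probability) pairs composing one word."""

    parts: tuple

    def __post_init__(self):
        word_surprisal_from_subtokens(self.parts)  # validates

    @property
    def surprisal(self):
        return word_surprisal_from_subtokens(self.parts)


# ---------------------------------------------------------------------------
# attaching predictor columns to event tables


def attach_predictors(events: pd.DataFrame, columns: dict, standardize=True, train_mask=None):
    """Attach named predictor vectors to an event table.

    When standardizing, the mean/SD are computed on the training partition
    (``train_mask``, all rows by default) and recorded in
    ``events.attrs["predictor_stats"]`` for reuse at prediction time.
    Constant columns are rejected.  Returns the augmented copy.
    """
    out = events.copy()
    out.attrs = dict(events.attrs)
    stats = dict(out.attrs.get("predictor_stats", {}))
    mask = np.ones(len(events), bool) if train_mask is None else np.asarray(train_mask, bool)
    for name, values in columns.items():
        v = np.asarray(values, float)
        if len(v) != len(events):
            raise ValueError(
                f"column {name!r} has {len(v)} values for {len(events)} events"
            )
        if standardize:
            m, s = float(v[mask].mean()), float(v[mask].std())
            if s == 0:
                raise ValueError(f"predictor {name!r} is constant (zero SD)")
            out[name] = (v - m) / s
            stats[name] = (m, s)
        else:
            out[name] = v
    out.attrs["predictor_stats"] = stats
    return out


def detach_predictors(events: pd.DataFrame, names):
    """Drop predictor columns (inverse of attach)."""
    out = events.drop(columns=list(names))
    out.attrs = dict(events.attrs)
    stats = dict(out.attrs.get("predictor_stats", {}))
    for n in names:
        stats.pop(n, None)
    out.attrs["predictor_stats"] = stats
    return out


# ---------------------------------------------------------------------------
# plain-text serialization


def write_counts(counts: CorpusCounts, path, order: int):
    """Sorted "ngram<TAB>count" lines for one order."""
    table = counts.counts[order]
    with open(path, "w") as fh:
        for ng in sorted(table):
            fh.write(" ".join(ng) + "\t" + str(table[ng]) + "\n")


def read_counts(paths_by_order: dict) -> CorpusCounts:
    """Rebuild CorpusCounts from per-order count files."""
    counts = CorpusCounts(max_order=max(paths_by_order))
    for order, path in sorted(paths_by_order.items()):
        table = {}
        with open(path) as fh:
            for line in fh:
                ng, c = line.rstrip("\n").split("\t")
                table[tuple(ng.split(" "))] = int(c)
        counts.counts[order] = table
    counts.total = sum(counts.counts.get(1, {}).values())
    return counts


def read_subtoken_logprobs(path) -> list:
    """Read a word_index/subtoken/logprob TSV into per-word
    SubtokenLogProbs, ordered by word index."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, grp in df.groupby("word_index", sort=True):
        out.append(SubtokenLogProbs(tuple(zip(grp["subtoken"], grp["logprob"].astype(float)))))
    return out
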