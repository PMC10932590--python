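"""Surprisal predictors: counting, Kneser-Ney smoothing, chain rule.

The Kneser-Ney implementation is checked against a brute-force oracle
written directly from the interpolated-KN definition (explicit loops over
raw token lists, no shared code with the package).
"""

from collections import Counter

import numpy as np
import pytest

from ctdreg.predictors import (
    BOS,
    EOS,
    UNK,
    KN_DISCOUNT,
    SubtokenLogProbs,
    attach_predictors,
    count_ngrams,
    detach_predictors,
    ngram_surprisal,
    tokenize,
    unigram_surprisal,
    word_surprisal_from_subtokens,
)

# ---------------------------------------------------------------------------
# brute-force interpolated Kneser-Ney oracle


def _oracle_tables(sentences, order):
    """Raw n-gram counts of a given order with BOS/EOS padding."""
    table = Counter()
    for sent in sentences:
        padded = [BOS] * (order - 1) + list(sent) + [EOS]
        for i in range(len(padded) - order + 1):
            table[tuple(padded[i : i + order])] += 1
    return table


def _oracle_kn(sentences, context, word, order, D=KN_DISCOUNT, highest=True):
    """Interpolated KN by direct summation.

    Highest order: raw counts.  Lower orders: continuation counts (number
    of distinct left extensions).  Base case: word types by corpus count,
    EOS by sentence count, UNK by one pseudo-count.
    """
    vocab = {w for s in sentences for w in s}
    if order == 1:
        uni = Counter(w for s in sentences for w in s)
        total = sum(uni.values())
        n_eos = len(sentences)
        denom = total + n_eos + 1
        if word == EOS:
            return n_eos / denom
        if word in uni:
            return uni[word] / denom
        return 1.0 / denom
    if highest:
        table = _oracle_tables(sentences, order)
    else:
        bigger = _oracle_tables(sentences, order + 1)
        table = Counter()
        for ng in bigger:
            table[ng[1:]] += 1
    ctx_total = sum(c for ng, c in table.items() if ng[:-1] == context)
    n_types = sum(1 for ng in table if ng[:-1] == context)
    lower = _oracle_kn(sentences, context[1:], word, order - 1, D, highest=False)
    if ctx_total == 0:
        return lower
    c_ng = table.get(context + (word,), 0)
    return max(c_ng - D, 0.0) / ctx_total + D * n_types / ctx_total * lower


TOY = [["a", "b", "a", "c"], ["b", "a", "b"]]  # 7 tokens, <= 10


# ---------------------------------------------------------------------------
# counting


def test_unigram_counts():
    counts = count_ngrams(["a", "a", "b"], 1)
    assert counts.count(("a",)) == 2
    assert counts.count(("b",)) == 1
    assert counts.total == 3


def test_bigram_counts():
    counts = count_ngrams(["a", "b", "a", "b"], 2)
    assert counts.count(("a", "b")) == 2
    assert counts.count(("b", "a")) == 1
    assert counts.count((BOS, "a")) == 1
    assert counts.count(("b", EOS)) == 1


def test_unigram_counts_conserve_total():
    counts = count_ngrams(TOY, 3)
    assert sum(counts.counts[1].values()) == counts.total == 7


def test_empty_corpus_rejected():
    with pytest.raises(ValueError):
        count_ngrams([], 1)
    with pytest.raises(ValueError):
        count_ngrams([[]], 2)


# ---------------------------------------------------------------------------
# unigram surprisal


def test_unigram_surprisal_hand_computed():
    counts = count_ngrams(["a", "a", "b"], 1)
    assert unigram_surprisal(counts, "a") == pytest.approx(-np.log(2 / 3))
    assert unigram_surprisal(counts, "a") < unigram_surprisal(counts, "b")


def test_unigram_surprisal_normalizes_over_vocab():
    counts = count_ngrams(TOY, 1)
    total = sum(np.exp(-unigram_surprisal(counts, w)) for w in counts.vocab)
    assert total == pytest.approx(1.0)


def test_unknown_word_gets_finite_surprisal():
    counts = count_ngrams(["a", "a", "b"], 1)
    s = unigram_surprisal(counts, "zzz")
    assert s == pytest.approx(-np.log(1 / 4))


# ---------------------------------------------------------------------------
# Kneser-Ney


@pytest.mark.parametrize("order", [2, 3])
def test_kn_matches_bruteforce_oracle_everywhere(order):
    counts = count_ngrams(TOY, 3)
    vocab = sorted(counts.vocab | {EOS, UNK})
    contexts = sorted(
        {ng[:-1] for ng in counts.counts[order]} | {("x", "y")[: order - 1]}
    )
    for ctx in contexts:
        for w in vocab:
            got = np.exp(-ngram_surprisal(counts, ctx, w, order))
            want = _oracle_kn(TOY, ctx, UNK if w == UNK else w, order)
            assert got == pytest.approx(want, abs=1e-12), (ctx, w)


@pytest.mark.parametrize("order", [2, 3])
def test_kn_conditionals_normalize(order):
    counts = count_ngrams(TOY, 3)
    vocab = counts.vocab | {EOS, UNK}
    for ctx in [("a",), ("b",), ("zz",)][: 3 if order == 2 else 2] + (
        [("a", "b"), ("zz", "a")] if order == 3 else []
    ):
        ctx = ctx if len(ctx) == order - 1 else (BOS,) * (order - 1 - len(ctx)) + ctx
        total = sum(np.exp(-ngram_surprisal(counts, ctx, w, order)) for w in vocab)
        assert total == pytest.approx(1.0, abs=1e-9), ctx


def test_kn_unseen_context_backs_off():
    counts = count_ngrams(TOY, 2)
    got = np.exp(-ngram_surprisal(counts, ("never-seen",), "a", 2))
    want = _oracle_kn(TOY, ("never-seen",), "a", 1, highest=False)
    assert got == pytest.approx(want)


def test_kn_order_validation():
    counts = count_ngrams(TOY, 2)
    with pytest.raises(ValueError):
        ngram_surprisal(counts, ("a",), "b", 4)
    with pytest.raises(ValueError):
        ngram_surprisal(counts, ("a", "b"), "c", 3)  # counts only to order 2


# ---------------------------------------------------------------------------
# subtoken chain rule


def test_subtoken_surprisal_examples():
    assert word_surprisal_from_subtokens([("cau", -2.0), ("ldron", -1.5)]) == 3.5
    assert word_surprisal_from_subtokens([("w", -0.7)]) == pytest.approx(0.7)


def test_subtoken_split_invariance():
    # same joint probability, different granularity
    one = word_surprisal_from_subtokens([("abcd", -3.2)])
    two = word_surprisal_from_subtokens([("ab", -1.9), ("cd", -1.3)])
    assert one == pytest.approx(two)


def test_subtoken_validation():
    with pytest.raises(ValueError):
        word_surprisal_from_subtokens([])
    with pytest.raises(ValueError):
        word_surprisal_from_subtokens([("a", 0.5)])
    with pytest.raises(ValueError):
        SubtokenLogProbs((("a", float("-inf")),))


def test_tokenize_strips_punctuation():
    assert tokenize("The cat, the 'dog'!") == ["the", "cat", "the", "dog"]
    assert tokenize("Hello", lowercase=False) == ["Hello"]


# ---------------------------------------------------------------------------
# attaching predictors


def test_attach_standardizes_and_detaches(small_sim):
    ev = small_sim["events"][
        ["participant_id", "text_id", "sentence_index", "token_position", "time_s"]
    ].copy()
    col = np.arange(len(ev), dtype=float)
    out = attach_predictors(ev, {"extra": col})
    assert out["extra"].mean() == pytest.approx(0.0, abs=1e-12)
    assert out["extra"].to_numpy().std() == pytest.approx(1.0, rel=1e-6)
    m, s = out.attrs["predictor_stats"]["extra"]
    assert np.allclose(out["extra"] * s + m, col)
    back = detach_predictors(out, ["extra"])
    assert list(back.columns) == list(ev.columns)


def test_attach_rejects_bad_columns(small_sim):
    ev = small_sim["events"]
    with pytest.raises(ValueError):
        attach_predictors(ev, {"bad": np.ones(3)})
    with pytest.raises(ValueError):
        attach_predictors(ev, {"const": np.ones(len(ev))})
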