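"""Supervised query expansion with tf.rf term weighting.

Given a gold-annotated collection, each method's annotated passage
texts form the positive category and every other method's annotated
passages form the negative category.  Each token seen in the positive
category is weighted with term frequency x relevance frequency:

    tf.rf = tf * log2(2 + a / max(1, c))

where ``tf`` is the token's occurrence count in positive passages,
``a`` the number of positive passages containing it and ``c`` the
number of negative passages containing it.  Tokens frequent in the
positive category relative to the negative one score highest.

The ranked tokens feed two expansion tiers: Tier 1 terms carry weight
0.50 and Tier 2 terms 0.25 (half and a quarter of a name match).
Tier selection is either top-k (e.g. the f7s7 and f10s10
configurations: first 7 / next 7, first 10 / next 10) or manual lists
curated by a human from the same ranking.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .bioc import ANNOTATION_TYPE, BiocCollection, local_method_id
from .preprocess import tokenize
from .queries import (
    MethodLexicon,
    MethodQuery,
    QueryTable,
    ScoredTerm,
    TIER_WEIGHTS,
    build_baseline_queries,
    normalize_term,
)


class TierConfigError(ValueError):
    """Raised when tier-list construction is misconfigured."""


@dataclass(frozen=True)
class TfRfCounts:
    """Token statistics feeding the tf.rf weight.

    tf: token occurrences in positive-category passages;
    a: positive passages containing the token;
    c: negative passages containing the token.
    """

    tf: int
    a: int
    c: int


def tfrf_weight(counts: TfRfCounts) -> float:
    """tf * log2(2 + a / max(1, c)); the max() guards c == 0."""
    return counts.tf * math.log2(2.0 + counts.a / max(1, counts.c))


def _annotation_texts(gold: BiocCollection):
    """Yield (local method id, annotation text) over a gold collection."""
    for doc in gold.documents:
        for passage in doc.passages:
            for ann in passage.annotations:
                if ann.infons.get("type") != ANNOTATION_TYPE:
                    continue
                method = ann.infons.get("PSIMI")
                if method is not None:
                    yield method, ann.text


def rank_terms(gold: BiocCollection, method_id: str) -> list[tuple[str, float]]:
    """Rank the positive-category tokens of *method_id* by tf.rf weight.

    A passage annotated with several methods counts as positive for
    each of its own methods and negative for all others.  Returns
    ``(token, weight)`` pairs sorted by descending weight, ties broken
    lexicographically; empty if the method has no gold passages.
    """
    target = local_method_id(method_id)
    positive: list[list[str]] = []
    negative: list[list[str]] = []
    for method, text in _annotation_texts(gold):
        tokens = tokenize(text)
        (positive if method == target else negative).append(tokens)
    if not positive:
        return []
    tf = Counter()
    a = Counter()
    for tokens in positive:
        tf.update(tokens)
        a.update(set(tokens))
    c = Counter()
    for tokens in negative:
        c.update(set(tokens))
    ranked = [
        (token, tfrf_weight(TfRfCounts(tf[token], a[token], c[token])))
        for token in tf
    ]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


@dataclass
class TierLists:
    """Tier 1 (weight 0.50) and Tier 2 (weight 0.25) expansion terms."""

    tier1: list[ScoredTerm] = field(default_factory=list)
    tier2: list[ScoredTerm] = field(default_factory=list)


def build_tier_lists(
    ranked: list[tuple[str, float]],
    names: list[str],
    mode: str = "topk",
    k1: int = 7,
    k2: int = 7,
    manual_lists: tuple[list[str], list[str]] | None = None,
) -> TierLists:
    """Assign ranked tokens to the two expansion tiers.

    Method names are excluded from the tiers even when they rank high,
    since they are already in the initial query.  Exclusion is
    exact-string on the normalized token (a hyphenated variant of a
    multi-word name, e.g. ``pull-down`` for ``pull down``, is a
    legitimate tier term).  ``topk`` mode takes the first *k1*
    surviving tokens as Tier 1 and the next *k2* as Tier 2; ``manual``
    mode uses caller-curated lists.
    """
    if mode == "manual":
        if manual_lists is None:
            raise TierConfigError("manual mode requires manual_lists")
        tier1_terms, tier2_terms = manual_lists
    elif mode == "topk":
        if k1 < 0 or k2 < 0:
            raise TierConfigError("k1 and k2 must be non-negative")
        name_set = {normalize_term(n) for n in names}
        survivors = [term for term, _ in ranked if term not in name_set]
        tier1_terms = survivors[:k1]
        tier2_terms = survivors[k1 : k1 + k2]
    else:
        raise TierConfigError(f"unknown tier mode {mode!r}")
    name_set = {normalize_term(n) for n in names}
    tier1_terms = [t for t in tier1_terms if normalize_term(t) not in name_set]
    tier2_terms = [t for t in tier2_terms if normalize_term(t) not in name_set
                   and t not in tier1_terms]
    return TierLists(
        tier1=[ScoredTerm(normalize_term(t), TIER_WEIGHTS["tier1"], "tier1")
               for t in tier1_terms],
        tier2=[ScoredTerm(normalize_term(t), TIER_WEIGHTS["tier2"], "tier2")
               for t in tier2_terms],
    )


def expand_query(query: MethodQuery, tiers: TierLists) -> MethodQuery:
    """Append tier terms to a baseline query, skipping duplicates."""
    existing = query.term_strings()
    terms = list(query.terms)
    for term in [*tiers.tier1, *tiers.tier2]:
        if term.term not in existing:
            terms.append(term)
            existing.add(term.term)
    return MethodQuery(query.method_id, terms)


def build_tfrf_table(
    gold: BiocCollection,
    lexicon: MethodLexicon,
    mode: str = "topk",
    k1: int = 7,
    k2: int = 7,
    manual_lists: dict[str, tuple[list[str], list[str]]] | None = None,
) -> QueryTable:
    """Baseline queries expanded with tf.rf tiers learned from *gold*."""
    baseline = build_baseline_queries(lexicon)
    queries = {}
    for method_id, query in baseline.queries.items():
        ranked = rank_terms(gold, method_id)
        method_manual = None
        if manual_lists is not None:
            method_manual = manual_lists.get(method_id, ([], []))
        if mode == "manual" and method_manual is None:
            raise TierConfigError("manual mode requires manual_lists")
        tiers = build_tier_lists(
            ranked,
            lexicon.names(method_id),
            mode=mode,
            k1=k1,
            k2=k2,
            manual_lists=method_manual,
        )
        queries[method_id] = expand_query(query, tiers)
    return QueryTable(queries)
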