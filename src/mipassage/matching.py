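"""Query matching: sentence scoring, neighbour extension and annotation.

Sentences of every eligible paragraph are scored against the query
table.  A sentence whose top-scoring method reaches the main threshold
becomes a seed; its immediate previous/next sentences join the passage
when their own best method is the same and reaches the (lower)
neighbour threshold.  Maximal runs of consecutive same-method
sentences merge into a single passage annotation.

Score aggregation is additive for the baseline and tf.rf query tables
(a name scores 1.0; one Tier 1 plus two Tier 2 terms reach
0.50 + 0.25 + 0.25 = 1.0) and takes the maximum matched weight for
embedding queries (a single neighbour's cosine is compared against the
0.9 / 0.65 thresholds).  Both aggregations are available in every mode.

An optional entity gate discards candidate passages lacking at least
one protein name and one interaction keyword, emulating the behaviour
of a named-entity tagger plus an ontology keyword list with plain
gazetteers.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field, replace

from .bioc import BiocCollection, BiocDocument, append_annotation
from .preprocess import (
    EXCLUDED_INFON_TYPES,
    MIN_WORDS,
    eligible_paragraph,
    split_sentences,
    tokenize,
)
from .queries import MethodQuery, QueryTable, ScoredTerm, normalize_term

logger = logging.getLogger(__name__)

_WORD_SPLIT = re.compile(r"[\s-]+")


class GateConfigError(ValueError):
    """Raised when the entity gate is enabled but unusable."""


@dataclass(frozen=True)
class MatchConfig:
    """Thresholds and mode switches for the matcher.

    Defaults follow the mode: baseline and tf.rf use main threshold
    1.0, neighbour threshold 0.5 and additive aggregation; embedding
    mode uses 0.9 / 0.65 and maximum aggregation.  Threshold
    comparisons are always >=.
    """

    mode: str = "baseline"
    main_threshold: float = 1.0
    neighbor_threshold: float = 0.5
    aggregation: str = "additive"
    gate_enabled: bool = False
    multi_label_baseline: bool = True

    def __post_init__(self):
        if self.mode not in ("baseline", "tfrf", "embedding"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.aggregation not in ("additive", "maximum"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if not 0 < self.neighbor_threshold <= self.main_threshold:
            raise ValueError(
                "thresholds must satisfy 0 < neighbor_threshold <= main_threshold"
            )

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "MatchConfig":
        if mode == "embedding":
            defaults = dict(mode=mode, main_threshold=0.9,
                            neighbor_threshold=0.65, aggregation="maximum")
        else:
            defaults = dict(mode=mode, main_threshold=1.0,
                            neighbor_threshold=0.5, aggregation="additive")
        defaults.update(overrides)
        return cls(**defaults)

    def with_gate(self, enabled: bool = True) -> "MatchConfig":
        return replace(self, gate_enabled=enabled)


def _load_gazetteer(path) -> set[str]:
    terms = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.add(normalize_term(line))
    return terms


@dataclass
class EntityGate:
    """Protein and interaction-keyword gazetteers for the passage gate."""

    proteins: set[str] = field(default_factory=set)
    keywords: set[str] = field(default_factory=set)

    @classmethod
    def from_files(cls, proteins_path, keywords_path) -> "EntityGate":
        return cls(
            proteins=_load_gazetteer(proteins_path),
            keywords=_load_gazetteer(keywords_path),
        )

    def validate(self) -> None:
        if not self.proteins or not self.keywords:
            raise GateConfigError("entity gate requires non-empty gazetteers")


def _expand_tokens(tokens: list[str]) -> list[str]:
    """Split hyphenated tokens so space/hyphen term variants unify."""
    expanded = []
    for token in tokens:
        expanded.extend(w for w in token.split("-") if w)
    return expanded


def term_in_sentence(term: str, tokens: list[str]) -> bool:
    """True iff the term's words occur as a contiguous token run.

    Hyphen and space variants are unified on both sides: the term
    ``pull down`` matches the token ``pull-down`` and vice versa.
    Matching is exact per word — no stemming (``two hybrid`` does not
    match ``two hybrids``).
    """
    words = [w for w in _WORD_SPLIT.split(term.lower()) if w]
    if not words:
        return False
    sequence = _expand_tokens(tokens)
    n = len(words)
    return any(sequence[i : i + n] == words for i in range(len(sequence) - n + 1))


def matched_terms(tokens: list[str], query: MethodQuery) -> list[ScoredTerm]:
    """Distinct query terms present in the token list."""
    return [st for st in query.terms if term_in_sentence(st.term, tokens)]


def score_sentence(
    tokens: list[str],
    query: MethodQuery,
    config: MatchConfig,
) -> float:
    """Aggregate the weights of the distinct matched terms.

    Additive aggregation sums the weights (a repeated match of the
    same term counts once); maximum aggregation takes the single best
    weight.  Returns 0 when nothing matches.
    """
    matched = matched_terms(tokens, query)
    if not matched:
        return 0.0
    scores = [st.score for st in matched]
    return sum(scores) if config.aggregation == "additive" else max(scores)


def entity_gate(passage_text: str, proteins: set[str], keywords: set[str]) -> bool:
    """True iff the passage mentions >= 1 protein and >= 1 keyword."""
    if not proteins or not keywords:
        raise GateConfigError("entity gate requires non-empty gazetteers")
    tokens = tokenize(passage_text)
    has_protein = any(term_in_sentence(p, tokens) for p in proteins)
    if not has_protein:
        return False
    return any(term_in_sentence(k, tokens) for k in keywords)


def _runs(indices: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers as (first, last) pairs."""
    runs = []
    for i in sorted(indices):
        if runs and i == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], i)
        else:
            runs.append((i, i))
    return runs


def _annotate_document_inplace(
    doc: BiocDocument,
    table: QueryTable,
    config: MatchConfig,
    gate: EntityGate | None,
    excluded_types,
    min_words: int,
    counter: int,
) -> int:
    if config.gate_enabled:
        if gate is None:
            raise GateConfigError("gate enabled but no EntityGate supplied")
        gate.validate()
    for passage in doc.passages:
        if not eligible_paragraph(passage, excluded_types, min_words):
            continue
        sentences = split_sentences(passage.text, base_offset=passage.offset)
        if not sentences:
            continue
        token_lists = [tokenize(s.text) for s in sentences]
        per_method: list[dict[str, float]] = []
        for tokens in token_lists:
            scores = {}
            for query in table:
                score = score_sentence(tokens, query, config)
                if score > 0.0:
                    scores[query.method_id] = score
            per_method.append(scores)
        best_method: list[str | None] = []
        best_score: list[float] = []
        for scores in per_method:
            if scores:
                top = max(scores.values())
                # tie-break: numerically smallest PSI-MI id
                method = min(m for m, s in scores.items() if s == top)
                best_method.append(method)
                best_score.append(top)
            else:
                best_method.append(None)
                best_score.append(0.0)
        labels: list[set[str]] = [set() for _ in sentences]
        multi_label = config.mode == "baseline" and config.multi_label_baseline
        for i, scores in enumerate(per_method):
            if multi_label:
                labels[i].update(
                    m for m, s in scores.items() if s >= config.main_threshold
                )
            elif best_method[i] is not None and best_score[i] >= config.main_threshold:
                labels[i].add(best_method[i])
        seeds = [set(l) for l in labels]
        for i, seed_methods in enumerate(seeds):
            for method in seed_methods:
                for j in (i - 1, i + 1):
                    if 0 <= j < len(sentences) and method not in labels[j]:
                        if (
                            best_method[j] == method
                            and best_score[j] >= config.neighbor_threshold
                        ):
                            labels[j].add(method)
        all_methods = sorted(set().union(*labels)) if labels else []
        for method in all_methods:
            indices = [i for i, l in enumerate(labels) if method in l]
            for first, last in _runs(indices):
                start = sentences[first].offset
                end = sentences[last].end
                text = passage.text[start - passage.offset : end - passage.offset]
                if config.gate_enabled and not entity_gate(
                    text, gate.proteins, gate.keywords
                ):
                    continue
                counter = append_annotation(
                    passage, method, (start, end - start), text, counter
                )
    return counter


def annotate_document(
    doc: BiocDocument,
    table: QueryTable,
    config: MatchConfig,
    gate: EntityGate | None = None,
    excluded_types=EXCLUDED_INFON_TYPES,
    min_words: int = MIN_WORDS,
    id_base: int = 0,
) -> BiocDocument:
    """Return a copy of *doc* with passage annotations appended.

    Ineligible paragraphs are untouched; a document without matches is
    returned unchanged (modulo the copy).  Annotation ids count up from
    *id_base* throughout the document.
    """
    doc = copy.deepcopy(doc)
    _annotate_document_inplace(
        doc, table, config, gate, excluded_types, min_words, id_base
    )
    return doc


def annotate_collection(
    collection: BiocCollection,
    table: QueryTable,
    config: MatchConfig,
    gate: EntityGate | None = None,
    excluded_types=EXCLUDED_INFON_TYPES,
    min_words: int = MIN_WORDS,
    id_base: int = 0,
) -> BiocCollection:
    """Annotate every document of a collection (ids document-scoped)."""
    collection = copy.deepcopy(collection)
    for doc in collection.documents:
        _annotate_document_inplace(
            doc, table, config, gate, excluded_types, min_words, id_base
        )
    return collection
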