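"""Unsupervised query expansion from word/phrase embeddings.

Each method's initial query terms are looked up in an embedding store
(word2vec text format; multi-word phrases are single tokens joined by
underscores on disk).  For every in-vocabulary initial term the top-n
cosine neighbours are pooled, then the pool is reduced by three steps,
applied in this order:

1. **combine** — keep one entry per distinct term (the highest cosine
   among its occurrences) and drop terms that are themselves a
   name/synonym of any method in the lexicon;
2. **clean** — cross-method: drop a term from method M when it
   contains another method's name as a word sub-phrase, or when it
   appears with a strictly higher cosine in another method's list;
3. **filter** — within a list, drop a term when a substring of it is
   present with a higher score (the shorter, higher-scoring variant
   wins).

Survivors join the query with their cosine scores as ``embedding``
tier terms; the initial terms keep weight 1.0.  Known-ambiguous
initial terms (e.g. the ``2h`` synonym of two hybrid) are removed
before expansion; the packaged default removal list has 15 entries.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .queries import (
    MethodLexicon,
    MethodQuery,
    QueryTable,
    ScoredTerm,
    normalize_term,
)

logger = logging.getLogger(__name__)

_WORD_SPLIT = re.compile(r"[\s-]+")


def _words(term: str) -> tuple[str, ...]:
    """Whitespace/hyphen-normalized word sequence of a term."""
    return tuple(w for w in _WORD_SPLIT.split(term.lower()) if w)


def _contains_words(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    if n == 0 or n > len(haystack):
        return False
    return any(haystack[i : i + n] == needle for i in range(len(haystack) - n + 1))


class EmbeddingFormatError(ValueError):
    """Raised for malformed word2vec text files."""


class EmbeddingStore:
    """Dense vectors for words and multi-word phrases.

    Lookups are case- and whitespace-normalized; phrases are stored
    with spaces in memory (underscores only on disk).  Cosines are
    computed on the raw vectors; a zero vector has similarity 0 to
    everything.
    """

    def __init__(self, vectors: dict[str, "np.ndarray"]):
        if not vectors:
            self._terms: list[str] = []
            self._matrix = np.zeros((0, 0))
        else:
            dims = {len(v) for v in vectors.values()}
            if len(dims) != 1:
                raise EmbeddingFormatError(f"mixed vector dimensions: {sorted(dims)}")
            self._terms = [normalize_term(t) for t in vectors]
            if len(set(self._terms)) != len(self._terms):
                raise EmbeddingFormatError("duplicate terms after normalization")
            self._matrix = np.asarray(
                [np.asarray(v, dtype=float) for v in vectors.values()]
            )
        self._index = {t: i for i, t in enumerate(self._terms)}
        self._norms = np.linalg.norm(self._matrix, axis=1) if self._terms else np.zeros(0)

    @property
    def vocabulary(self) -> set[str]:
        return set(self._terms)

    @property
    def dimension(self) -> int:
        return self._matrix.shape[1] if self._matrix.size else 0

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self._index

    def __len__(self) -> int:
        return len(self._terms)

    def vector(self, term: str) -> "np.ndarray":
        return self._matrix[self._index[normalize_term(term)]]

    def cosine(self, term_a: str, term_b: str) -> float:
        va, vb = self.vector(term_a), self.vector(term_b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0.0 or nb == 0.0:
            return 0.0
        return float(va @ vb / (na * nb))

    def similarities(self, term: str) -> "np.ndarray":
        """Cosine of *term* against the whole vocabulary (zeros guarded)."""
        v = self.vector(term)
        nv = np.linalg.norm(v)
        if nv == 0.0:
            return np.zeros(len(self._terms))
        denom = np.where(self._norms == 0.0, 1.0, self._norms) * nv
        sims = (self._matrix @ v) / denom
        sims[self._norms == 0.0] = 0.0
        return sims

    # -- word2vec text format ------------------------------------------------

    @classmethod
    def from_word2vec_text(cls, path) -> "EmbeddingStore":
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as handle:
            header = handle.readline().split()
            if len(header) != 2:
                raise EmbeddingFormatError(f"{path}: bad header {header!r}")
            n_terms, dim = int(header[0]), int(header[1])
            for lineno, line in enumerate(handle, start=2):
                parts = line.rstrip("\n").split(" ")
                if len(parts) < dim + 1:
                    raise EmbeddingFormatError(f"{path}:{lineno}: truncated vector")
                term = parts[0].replace("_", " ")
                vectors[term] = np.array([float(x) for x in parts[1 : dim + 1]])
        if len(vectors) != n_terms:
            raise EmbeddingFormatError(
                f"{path}: header announces {n_terms} terms, found {len(vectors)}"
            )
        return cls(vectors)

    def to_word2vec_text(self, path, precision: int = 6) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"{len(self._terms)} {self.dimension}\n")
            for term, row in zip(self._terms, self._matrix):
                token = term.replace(" ", "_")
                values = " ".join(f"{x:.{precision}f}" for x in row)
                handle.write(f"{token} {values}\n")


@dataclass(frozen=True)
class Candidate:
    """An expansion candidate with its cosine and provenance."""

    term: str
    score: float
    source: str  # the initial query term whose neighbourhood produced it


@dataclass
class CandidatePool:
    method_id: str
    candidates: list[Candidate] = field(default_factory=list)


@dataclass
class AmbiguousRemovals:
    """(method id, term) pairs to delete from initial queries."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def terms_for(self, method_id: str) -> set[str]:
        return {normalize_term(t) for mid, t in self.pairs if mid == method_id}

    @classmethod
    def load(cls, path) -> "AmbiguousRemovals":
        pairs = []
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                method_id, term = line.split("\t")
                pairs.append((method_id.strip(), normalize_term(term)))
        return cls(pairs)

    @classmethod
    def default(cls) -> "AmbiguousRemovals":
        resource = importlib.resources.files("mipassage.data") / "ambiguous_removals.tsv"
        with importlib.resources.as_file(resource) as path:
            return cls.load(path)


def nearest_neighbors(term: str, store: EmbeddingStore, n: int) -> list[ScoredTerm]:
    """Top-*n* cosine neighbours of *term*, excluding the term itself.

    Out-of-vocabulary terms yield an empty list (vectors cannot be
    built for every ontology synonym).  Ties are broken alphabetically
    for determinism.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    key = normalize_term(term)
    if key not in store:
        return []
    sims = store.similarities(key)
    scored = [
        (t, float(s)) for t, s in zip(store._terms, sims) if t != key
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return [ScoredTerm(t, s, "embedding") for t, s in scored[:n]]


def combine(pool: CandidatePool, lexicon: MethodLexicon) -> list[ScoredTerm]:
    """Deduplicate a candidate pool and drop ontology names.

    Keeps, per distinct term string, the occurrence with the highest
    cosine; then removes any term that is already a name or synonym of
    some method in the lexicon.  Output is sorted by descending score.
    """
    best: dict[str, float] = {}
    for cand in pool.candidates:
        term = normalize_term(cand.term)
        if term not in best or cand.score > best[term]:
            best[term] = cand.score
    all_names = lexicon.all_names()
    result = [
        ScoredTerm(term, score, "embedding")
        for term, score in best.items()
        if term not in all_names
    ]
    result.sort(key=lambda st: (-st.score, st.term))
    return result


def clean(
    lists: dict[str, list[ScoredTerm]],
    lexicon: MethodLexicon,
) -> dict[str, list[ScoredTerm]]:
    """Cross-method cleaning of combined candidate lists.

    A term is dropped from method M's list when (a) it contains, as a
    whitespace/hyphen-delimited word sub-phrase, a name from the
    initial query of another method, or (b) it appears in another
    method's list with a strictly higher cosine.  Score ties keep the
    term in both lists (and are logged) — only a strictly higher score
    evicts.  Both rules are evaluated against the input snapshot.
    """
    name_words = {
        mid: [_words(name) for name in names]
        for mid, names in lexicon.entries.items()
    }
    snapshot = {
        mid: {st.term: st.score for st in terms} for mid, terms in lists.items()
    }
    cleaned: dict[str, list[ScoredTerm]] = {}
    for mid, terms in lists.items():
        kept = []
        for st in terms:
            words = _words(st.term)
            contains_foreign_name = any(
                _contains_words(words, needle)
                for other, needles in name_words.items()
                if other != mid
                for needle in needles
            )
            if contains_foreign_name:
                continue
            beaten = False
            for other, scores in snapshot.items():
                if other == mid:
                    continue
                other_score = scores.get(st.term)
                if other_score is None:
                    continue
                if other_score > st.score:
                    beaten = True
                    break
                if other_score == st.score:
                    logger.info(
                        "clean: %r tied at %.6f between %s and %s; kept in both",
                        st.term, st.score, mid, other,
                    )
            if not beaten:
                kept.append(st)
        cleaned[mid] = kept
    return cleaned


def filter_substrings(
    candidates: list[ScoredTerm],
    word_boundary: bool = False,
) -> list[ScoredTerm]:
    """Drop terms that have a higher-scoring substring in the list.

    A term t is removed iff some other term u in the (input) list is a
    substring of t with ``score(u) > score(t)``.  By default substring
    is plain character containment on the normalized term; with
    ``word_boundary=True`` u must match as a whole-word sub-phrase.
    """
    def is_sub(u: ScoredTerm, t: ScoredTerm) -> bool:
        if word_boundary:
            return _contains_words(_words(t.term), _words(u.term))
        return u.term in t.term

    kept = []
    for t in candidates:
        removed = any(
            u.term != t.term and is_sub(u, t) and u.score > t.score
            for u in candidates
        )
        if not removed:
            kept.append(t)
    return kept


def expand_queries(
    baseline: QueryTable,
    store: EmbeddingStore,
    removals: AmbiguousRemovals | None = None,
    lexicon: MethodLexicon | None = None,
    n: int = 100,
) -> QueryTable:
    """Full embedding-based expansion: pool → combine → clean → filter.

    Per method: drop ambiguous initial terms, pool the top-*n*
    neighbours of each surviving in-vocabulary initial term, combine
    per method, clean once globally across methods, filter substrings
    per method, and append the survivors as ``embedding`` tier terms.
    Methods with no in-vocabulary initial terms keep their (pruned)
    baseline query and are logged.
    """
    if removals is None:
        removals = AmbiguousRemovals()
    if lexicon is None:
        lexicon = MethodLexicon(
            {q.method_id: [t.term for t in q.name_terms] for q in baseline}
        )
    initial: dict[str, list[str]] = {}
    combined: dict[str, list[ScoredTerm]] = {}
    for method_id, query in baseline.queries.items():
        drop = removals.terms_for(method_id)
        init_terms = [t.term for t in query.name_terms if t.term not in drop]
        initial[method_id] = init_terms
        pool = CandidatePool(method_id)
        in_vocab = [t for t in init_terms if t in store]
        if not in_vocab:
            logger.info(
                "method %s: no in-vocabulary initial terms; query not expanded",
                method_id,
            )
        for source in in_vocab:
            for neighbour in nearest_neighbors(source, store, n):
                pool.candidates.append(
                    Candidate(neighbour.term, neighbour.score, source)
                )
        combined[method_id] = combine(pool, lexicon)
    cleaned = clean(combined, lexicon)
    queries = {}
    for method_id, query in baseline.queries.items():
        terms = [ScoredTerm(t, 1.0, "name") for t in initial[method_id]]
        existing = {t.term for t in terms}
        for st in filter_substrings(cleaned[method_id]):
            if st.term not in existing:
                terms.append(st)
                existing.add(st.term)
        queries[method_id] = MethodQuery(method_id, terms)
    return QueryTable(queries)
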