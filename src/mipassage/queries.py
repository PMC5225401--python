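"""Method lexicon and weighted query model.

Each experimental interaction detection method in the PSI-MI ontology
(the subtree under MI:0045) has a canonical name and zero or more
synonyms.  The baseline retrieval query for a method is simply that
name list, every term carrying weight 1.0.  Query expansion (tf.rf
tiers or embedding neighbours) appends additional :class:`ScoredTerm`
entries with lower weights.

The lexicon file format is a flat TSV extract of the ontology:

    MI:0096<TAB>pull down
    MI:0018<TAB>two hybrid|two-hybrid|yeast two hybrid|...

i.e. one line per method, names pipe-separated, canonical name first.
A packaged default lexicon covers the 35 methods observed in the
annotated corpus, with full synonym lists for the methods whose
initial queries are documented.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .bioc import local_method_id

TIERS = ("name", "tier1", "tier2", "embedding")

#: Fixed weights of the supervised expansion tiers.
TIER_WEIGHTS = {"name": 1.0, "tier1": 0.50, "tier2": 0.25}


class LexiconError(ValueError):
    """Raised for malformed lexicon files."""


def normalize_term(term: str) -> str:
    """Lowercase and collapse internal whitespace."""
    return " ".join(term.lower().split())


@dataclass(frozen=True)
class ScoredTerm:
    """A query term with its weight and provenance tier.

    ``tier`` is one of ``name`` (ontology name/synonym, weight 1.0),
    ``tier1``/``tier2`` (supervised tf.rf terms, 0.50/0.25) or
    ``embedding`` (cosine similarity score of an expansion neighbour).
    """

    term: str
    score: float
    tier: str

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "name" and self.score != 1.0:
            raise ValueError("name-tier terms must have score 1.0")


@dataclass
class MethodLexicon:
    """Map of PSI-MI id → ordered name list (canonical name first)."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def names(self, method_id: str) -> list[str]:
        return self.entries.get(method_id, [])

    def all_names(self) -> set[str]:
        """Every name/synonym of every method, normalized."""
        return {name for names in self.entries.values() for name in names}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, method_id: str) -> bool:
        return method_id in self.entries


def load_lexicon(path) -> MethodLexicon:
    """Load a TSV lexicon (``id<TAB>name|synonym|...``)."""
    entries: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(f"{path}:{lineno}: expected 2 tab-separated columns")
            method_id, names_field = parts
            method_id = method_id.strip()
            if method_id in entries:
                raise LexiconError(f"{path}:{lineno}: duplicate id {method_id}")
            names = [normalize_term(n) for n in names_field.split("|") if n.strip()]
            if not names:
                raise LexiconError(f"{path}:{lineno}: empty name list for {method_id}")
            entries[method_id] = names
    return MethodLexicon(entries)


def default_lexicon() -> MethodLexicon:
    """The packaged lexicon of the 35 annotated PSI-MI methods."""
    resource = importlib.resources.files("mipassage.data") / "lexicon.tsv"
    with importlib.resources.as_file(resource) as path:
        return load_lexicon(path)


@dataclass
class MethodQuery:
    """One method's weighted term list (names first, then expansions)."""

    method_id: str
    terms: list[ScoredTerm] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for term in self.terms:
            if term.term in seen:
                raise ValueError(
                    f"query {self.method_id}: duplicate term {term.term!r}"
                )
            seen.add(term.term)

    @property
    def name_terms(self) -> list[ScoredTerm]:
        return [t for t in self.terms if t.tier == "name"]

    def term_strings(self) -> set[str]:
        return {t.term for t in self.terms}


@dataclass
class QueryTable:
    """All method queries, keyed by PSI-MI id."""

    queries: dict[str, MethodQuery] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.queries)

    def __getitem__(self, method_id: str) -> MethodQuery:
        return self.queries[method_id]

    def __iter__(self):
        return iter(self.queries.values())

    def save_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("method_id\tterm\tscore\ttier\n")
            for method_id in self.queries:
                for term in self.queries[method_id].terms:
                    handle.write(
                        f"{method_id}\t{term.term}\t{term.score!r}\t{term.tier}\n"
                    )

    @classmethod
    def load_tsv(cls, path) -> "QueryTable":
        queries: dict[str, list[ScoredTerm]] = {}
        with open(path, encoding="utf-8") as handle:
            header = handle.readline()
            if not header.startswith("method_id"):
                raise ValueError(f"{path}: missing query-table header")
            for line in handle:
                if not line.strip():
                    continue
                method_id, term, score, tier = line.rstrip("\n").split("\t")
                queries.setdefault(method_id, []).append(
                    ScoredTerm(term, float(score), tier)
                )
        return cls(
            {mid: MethodQuery(mid, terms) for mid, terms in queries.items()}
        )


def build_baseline_queries(lexicon: MethodLexicon) -> QueryTable:
    """One query per method: its ontology names, each with weight 1.0."""
    queries = {}
    for method_id, names in lexicon.entries.items():
        terms = []
        seen = set()
        for name in names:
            if name in seen:
                continue
            seen.add(name)
            terms.append(ScoredTerm(name, 1.0, "name"))
        queries[method_id] = MethodQuery(method_id, terms)
    return QueryTable(queries)


__all__ = [
    "LexiconError",
    "MethodLexicon",
    "MethodQuery",
    "QueryTable",
    "ScoredTerm",
    "TIER_WEIGHTS",
    "build_baseline_queries",
    "default_lexicon",
    "load_lexicon",
    "local_method_id",
    "normalize_term",
]
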