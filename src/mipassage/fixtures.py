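"""Deterministic synthetic fixtures: articles, lexicons and embeddings.

These generators build miniature BioC corpora with known planted
method passages, a toy lexicon, toy embedding stores with controlled
cosine structure, and the matching gazetteers, so every stage of the
pipeline is testable without external downloads.  Sentences are drawn
from a closed filler-word list disjoint from all method, protein and
keyword vocabulary, so tokenization and matching are fully
predictable.  A single integer seed determines every byte of output.

Planted paragraphs mirror the structure of the annotated corpus at
miniature scale: a filler sentence, then one or more consecutive
sentences that each mention a chosen method term variant together with
a protein name and an interaction keyword, then a trailing filler
sentence.  The gold annotation covers exactly the planted run.  Decoy
paragraphs carry an excluded infon type (or fewer than five words) and
mention a method name without being annotated, exercising the
eligibility filter.  Optional "layout" paragraphs mention a method
name in running prose without any protein or keyword and without gold
annotation — the false-positive shape the entity gate exists to
suppress.
"""

from __future__ import annotations

import copy
import math
import random
from dataclasses import dataclass, field

import numpy as np

from .bioc import BiocCollection, BiocDocument, BiocPassage, append_annotation
from .embeddings import EmbeddingStore
from .queries import MethodLexicon, normalize_term


class FixtureSpecError(ValueError):
    """Raised for inconsistent fixture specifications."""


class GenerationError(RuntimeError):
    """Raised when an embedding spec's cosine targets are infeasible."""


#: Closed filler vocabulary; shares no word with any toy method name,
#: protein or keyword (so filler sentences never match a query).
FILLER_WORDS = (
    "cells", "samples", "buffer", "lysate", "fraction", "culture",
    "overnight", "washed", "analyzed", "observed", "measured", "prepared",
    "incubated", "mixture", "aliquot", "gradient", "resolved", "loaded",
    "membrane", "signal", "levels", "values", "reported", "procedure",
)

TOY_PROTEINS = ("tbk1", "ddx3x", "irf3")
TOY_KEYWORDS = ("interacts", "interaction", "binds", "associates")


def toy_lexicon() -> MethodLexicon:
    """Four-method lexicon used by the default fixtures."""
    return MethodLexicon(
        {
            "MI:0018": ["two hybrid", "two-hybrid", "yeast two hybrid", "y2h"],
            "MI:0019": ["coimmunoprecipitation", "coip"],
            "MI:0096": ["pull down"],
            "MI:0676": ["tandem affinity purification", "tap tag"],
        }
    )


@dataclass
class FixtureSpec:
    """Recipe for a pair of (gold, bare) BioC collections.

    ``planted`` lists (method id, term variant, number of consecutive
    sentences) triples; each becomes one annotated paragraph, dealt
    round-robin across documents.  ``decoy_infon_fraction`` of the
    remaining paragraph slots get an excluded infon type containing a
    method name; ``layout_paragraphs`` adds per-document unannotated
    prose paragraphs mentioning a method name without protein/keyword.
    """

    n_documents: int = 2
    paragraphs_per_doc: int = 5
    sentence_length_range: tuple[int, int] = (6, 10)
    planted: list[tuple[str, str, int]] = field(
        default_factory=lambda: [
            ("MI:0096", "pull down", 1),
            ("MI:0018", "two hybrid", 2),
            ("MI:0019", "coimmunoprecipitation", 1),
        ]
    )
    decoy_infon_fraction: float = 0.25
    layout_paragraphs: int = 0
    seed: int = 13


def _filler_sentence(rng: random.Random, length_range: tuple[int, int]) -> str:
    n = rng.randint(*length_range)
    words = [rng.choice(FILLER_WORDS) for _ in range(n)]
    return " ".join(words) + " ."


def _planted_sentence(
    rng: random.Random,
    variant: str,
    length_range: tuple[int, int],
) -> str:
    protein = rng.choice(TOY_PROTEINS)
    keyword = rng.choice(TOY_KEYWORDS)
    n = max(2, rng.randint(*length_range) - 3)
    fillers = [rng.choice(FILLER_WORDS) for _ in range(n)]
    head, tail = fillers[: n // 2], fillers[n // 2 :]
    words = [*head, variant, protein, keyword, *tail]
    return " ".join(words) + " ."


def _layout_sentence(
    rng: random.Random,
    variant: str,
    length_range: tuple[int, int],
) -> str:
    n = max(2, rng.randint(*length_range) - 1)
    fillers = [rng.choice(FILLER_WORDS) for _ in range(n)]
    head, tail = fillers[: n // 2], fillers[n // 2 :]
    return " ".join([*head, variant, *tail]) + " ."


def generate_collection(
    spec: FixtureSpec,
    lexicon: MethodLexicon | None = None,
) -> tuple[BiocCollection, BiocCollection]:
    """Build (gold, bare): identical text, annotations only in gold."""
    lexicon = lexicon or toy_lexicon()
    for method_id, variant, n_sentences in spec.planted:
        if method_id not in lexicon:
            raise FixtureSpecError(f"planted method {method_id} not in lexicon")
        if n_sentences < 1:
            raise FixtureSpecError("planted runs need >= 1 sentence")
        if not normalize_term(variant):
            raise FixtureSpecError("empty planted term variant")
    rng = random.Random(spec.seed)
    all_names = sorted(lexicon.all_names())

    # Deal planted items round-robin over documents.
    per_doc_planted: list[list[tuple[str, str, int]]] = [
        [] for _ in range(spec.n_documents)
    ]
    for i, item in enumerate(spec.planted):
        per_doc_planted[i % spec.n_documents].append(item)
    needed = max((len(p) for p in per_doc_planted), default=0) + spec.layout_paragraphs
    if needed > spec.paragraphs_per_doc:
        raise FixtureSpecError(
            f"paragraphs_per_doc={spec.paragraphs_per_doc} too small for "
            f"{needed} planted/layout paragraphs in one document"
        )

    gold = BiocCollection(source="mipassage.fixtures", date="2016-01-01")
    for d in range(spec.n_documents):
        doc = BiocDocument(doc_id=f"FIX{d:04d}")
        planted_items = per_doc_planted[d]
        slots = list(range(spec.paragraphs_per_doc))
        reserved = rng.sample(slots, len(planted_items) + spec.layout_paragraphs)
        planted_slots = {slot: item for slot, item in zip(reserved, planted_items)}
        layout_slots = set(reserved[len(planted_items) :])
        offset = 0
        pending: list[tuple[BiocPassage, int, int, str]] = []
        for slot in slots:
            if slot in planted_slots:
                method_id, variant, n_sent = planted_slots[slot]
                pre = _filler_sentence(rng, spec.sentence_length_range)
                planted = [
                    _planted_sentence(rng, variant, spec.sentence_length_range)
                    for _ in range(n_sent)
                ]
                post = _filler_sentence(rng, spec.sentence_length_range)
                text = " ".join([pre, *planted, post])
                passage = BiocPassage(
                    offset=offset, infons={"type": "paragraph"}, text=text
                )
                span_start = offset + len(pre) + 1
                span_length = len(" ".join(planted))
                pending.append((passage, span_start, span_length, method_id))
            elif slot in layout_slots:
                variant = rng.choice(all_names)
                sentences = [
                    _filler_sentence(rng, spec.sentence_length_range),
                    _layout_sentence(rng, variant, spec.sentence_length_range),
                    _filler_sentence(rng, spec.sentence_length_range),
                ]
                passage = BiocPassage(
                    offset=offset,
                    infons={"type": "paragraph"},
                    text=" ".join(sentences),
                )
                pending.append((passage, -1, 0, ""))
            elif rng.random() < spec.decoy_infon_fraction:
                # Decoy: excluded infon type mentioning a method name,
                # or an over-short paragraph — never annotated.
                if rng.random() < 0.5:
                    name = rng.choice(all_names)
                    text = f"{name} {rng.choice(FILLER_WORDS)} " + " ".join(
                        rng.choice(FILLER_WORDS) for _ in range(5)
                    )
                    passage = BiocPassage(
                        offset=offset, infons={"type": "table"}, text=text
                    )
                else:
                    name = rng.choice(all_names)
                    passage = BiocPassage(
                        offset=offset,
                        infons={"type": "paragraph"},
                        text=f"{name} results",
                    )
                pending.append((passage, -1, 0, ""))
            else:
                n_sent = rng.randint(2, 4)
                text = " ".join(
                    _filler_sentence(rng, spec.sentence_length_range)
                    for _ in range(n_sent)
                )
                passage = BiocPassage(
                    offset=offset, infons={"type": "paragraph"}, text=text
                )
                pending.append((passage, -1, 0, ""))
            offset = passage.offset + len(passage.text) + 1
        counter = 0
        for passage, span_start, span_length, method_id in pending:
            doc.passages.append(passage)
            if span_start >= 0:
                text = passage.text[
                    span_start - passage.offset : span_start - passage.offset + span_length
                ]
                counter = append_annotation(
                    passage, method_id, (span_start, span_length), text, counter
                )
        gold.documents.append(doc)

    bare = copy.deepcopy(gold)
    for doc in bare.documents:
        for passage in doc.passages:
            passage.annotations.clear()
    return gold, bare


@dataclass
class ToyEmbeddingSpec:
    """Recipe for an embedding store with controlled cosine structure.

    Each cluster is (concept label, member terms, intra-cosine
    target): members are generated within a cone around a cluster-
    specific orthogonal axis so that every same-cluster pair has
    cosine >= the target, while cross-cluster cosines stay strictly
    below every intra-cluster target.
    """

    clusters: list[tuple[str, list[str], float]] = field(
        default_factory=lambda: [
            (
                "two-hybrid family",
                ["two-hybrid", "y2h", "split-ubiquitin", "interaction-trap"],
                0.95,
            ),
            (
                "pull-down family",
                ["pull down", "gst-pulldown", "glutathione bead capture"],
                0.95,
            ),
            (
                "coip family",
                ["coimmunoprecipitation", "co-ip assay", "antibody capture assay"],
                0.95,
            ),
        ]
    )
    dimension: int = 8
    seed: int = 29


def generate_embeddings(spec: ToyEmbeddingSpec) -> EmbeddingStore:
    """Materialize a :class:`ToyEmbeddingSpec`; verifies its guarantees."""
    if spec.dimension < 2:
        raise GenerationError("dimension must be >= 2")
    if spec.dimension < len(spec.clusters):
        raise GenerationError(
            "dimension must be >= number of clusters (orthogonal axes needed)"
        )
    for _, members, target in spec.clusters:
        if not 0.0 < target < 1.0:
            raise GenerationError(f"infeasible intra-cosine target {target}")
        if len(members) < 1:
            raise GenerationError("empty cluster")
    rng = np.random.default_rng(spec.seed)
    vectors: dict[str, np.ndarray] = {}
    memberships: list[list[str]] = []
    for axis, (_, members, target) in enumerate(spec.clusters):
        base = np.zeros(spec.dimension)
        base[axis] = 1.0
        # Members stay within half the cone angle that guarantees the
        # pairwise target, with a safety margin.
        phi_max = 0.5 * math.acos(target)
        cluster_terms = []
        for member in members:
            noise = rng.normal(size=spec.dimension)
            noise -= noise @ base * base
            norm = np.linalg.norm(noise)
            if norm == 0.0:
                noise = np.zeros(spec.dimension)
            else:
                noise /= norm
            theta = rng.uniform(0.0, 0.8 * phi_max)
            vector = math.cos(theta) * base + math.sin(theta) * noise
            scale = rng.uniform(0.5, 2.0)  # raw magnitudes vary; cosine invariant
            term = normalize_term(member)
            if term in vectors:
                raise GenerationError(f"duplicate member term {term!r}")
            vectors[term] = vector * scale
            cluster_terms.append(term)
        memberships.append(cluster_terms)
    store = EmbeddingStore(vectors)
    # Verify the advertised cosine structure numerically.
    min_target = min(t for _, _, t in spec.clusters)
    for (_, _, target), terms in zip(spec.clusters, memberships):
        for i, a in enumerate(terms):
            for b in terms[i + 1 :]:
                if store.cosine(a, b) < target:
                    raise GenerationError(
                        f"intra-cluster cosine({a!r}, {b!r}) below target {target}"
                    )
    for ci, terms_a in enumerate(memberships):
        for terms_b in memberships[ci + 1 :]:
            for a in terms_a:
                for b in terms_b:
                    if store.cosine(a, b) >= min_target:
                        raise GenerationError(
                            f"cross-cluster cosine({a!r}, {b!r}) reaches targets"
                        )
    return store


def toy_gazetteers() -> tuple[list[str], list[str]]:
    """(proteins, keywords) matching the planted fixture sentences."""
    return list(TOY_PROTEINS), list(TOY_KEYWORDS)
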