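"""Passage-level evaluation with Jaccard and partial Jaccard distances.

System output is compared with the gold annotations paragraph by
paragraph.  Two annotations match when they carry the same method id
(optionally after remapping, or ignoring ids entirely) and share some
text.  Passages are treated as character strings; the intersection of
a matched pair is the shorter passage when one covers the other, and
otherwise the longest common substring.  For a matched pair with
passage texts M (gold) and S (system):

    J    = |M ∩ S| / |M ∪ S|          → added to TP
    pdJM = |M| / |M ∪ S| − J          → added to FN (missed gold text)
    pdJS = |S| / |M ∪ S| − J          → added to FP (spurious system text)

pdJM + pdJS = 1 − J always holds.  Unmatched gold annotations add 1.0
to FN and unmatched system annotations add 1.0 to FP (Jaccard distance
of a completely missed passage is 1).  Precision, recall and F-measure
follow from the fractional TP/FP/FN totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from difflib import SequenceMatcher

from .bioc import BiocCollection
from .bioc import local_method_id

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Raised when gold and system collections are not comparable."""


def intersection_text(m: str, s: str) -> str:
    """The intersection string of two passages.

    If one passage covers the other the shorter one is the
    intersection (identical passages are their own intersection);
    otherwise the longest common contiguous substring, ties resolved
    to the earliest occurrence in *m*.  Either input empty → "".
    """
    if not m or not s:
        return ""
    if m in s:
        return m
    if s in m:
        return s
    matcher = SequenceMatcher(None, m, s, autojunk=False)
    match = matcher.find_longest_match(0, len(m), 0, len(s))
    return m[match.a : match.a + match.size]


@dataclass
class PassagePair:
    """A gold/system passage pair with its character-level overlap."""

    M: str
    S: str
    m_len: int
    s_len: int
    inter_len: int

    @classmethod
    def from_texts(cls, m: str, s: str) -> "PassagePair":
        inter = intersection_text(m, s)
        return cls(M=m, S=s, m_len=len(m), s_len=len(s), inter_len=len(inter))

    @property
    def union_len(self) -> int:
        return self.m_len + self.s_len - self.inter_len


def jaccard(pair: PassagePair) -> float:
    """|M ∩ S| / |M ∪ S|; two empty passages score 0 (and are logged)."""
    if pair.union_len == 0:
        logger.warning("Jaccard of two empty passages; defined as 0")
        return 0.0
    return pair.inter_len / pair.union_len


def partial_distances(pair: PassagePair) -> tuple[float, float]:
    """(pdJM, pdJS): the FN and FP shares of the pair's mismatch.

    pdJM = |M|/|M ∪ S| − J measures gold text the system missed;
    pdJS = |S|/|M ∪ S| − J measures system text beyond the gold span.
    Both are 0 for an exact match and they always sum to 1 − J.
    """
    union = pair.union_len
    if union == 0:
        return 0.0, 0.0
    j = jaccard(pair)
    return pair.m_len / union - j, pair.s_len / union - j


@dataclass
class EvalCounts:
    """Fractional true/false positive and false negative accumulators."""

    tp: float = 0.0
    fp: float = 0.0
    fn: float = 0.0

    def __iadd__(self, other: "EvalCounts") -> "EvalCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


@dataclass(frozen=True)
class Scores:
    precision: float
    recall: float
    f_measure: float

    @classmethod
    def from_counts(cls, counts: EvalCounts) -> "Scores":
        tp, fp, fn = counts.tp, counts.fp, counts.fn
        if tp + fp == 0:
            logger.info("precision denominator 0; reporting 0")
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            logger.info("recall denominator 0; reporting 0")
            recall = 0.0
        else:
            recall = tp / (tp + fn)
        if precision + recall == 0:
            f_measure = 0.0
        else:
            f_measure = 2 * precision * recall / (precision + recall)
        return cls(precision, recall, f_measure)


#: Remap treating the two coimmunoprecipitation subtypes as their parent.
COIP_REMAP = {"0006": "0019", "0007": "0019"}


@dataclass
class EvalOptions:
    """Evaluation variants.

    ``method_remap`` rewrites method ids on both sides before matching
    (the coip variant maps anti bait/anti tag coimmunoprecipitation,
    0006 and 0007, onto coimmunoprecipitation, 0019).  ``id_agnostic``
    drops the id requirement entirely: any overlapping passage pair
    can match.
    """

    method_remap: dict[str, str] = field(default_factory=dict)
    id_agnostic: bool = False

    @classmethod
    def coip(cls, id_agnostic: bool = False) -> "EvalOptions":
        return cls(method_remap=dict(COIP_REMAP), id_agnostic=id_agnostic)

    def effective_id(self, method_id: str | None) -> str | None:
        if method_id is None:
            return None
        local = local_method_id(method_id)
        return self.method_remap.get(local, local)


def _match_paragraph(
    gold_anns,
    system_anns,
    options: EvalOptions,
) -> EvalCounts:
    counts = EvalCounts()
    candidates = []
    for gi, g in enumerate(gold_anns):
        for si, s in enumerate(system_anns):
            if not options.id_agnostic:
                if options.effective_id(g.method_id) != options.effective_id(
                    s.method_id
                ):
                    continue
            pair = PassagePair.from_texts(g.text, s.text)
            if pair.inter_len == 0:
                continue
            candidates.append((jaccard(pair), gi, si, pair))
    # Greedy one-to-one pairing by descending Jaccard.
    candidates.sort(key=lambda item: (-item[0], item[1], item[2]))
    used_gold: set[int] = set()
    used_system: set[int] = set()
    for j, gi, si, pair in candidates:
        if gi in used_gold or si in used_system:
            continue
        used_gold.add(gi)
        used_system.add(si)
        pd_m, pd_s = partial_distances(pair)
        counts.tp += j
        counts.fn += pd_m
        counts.fp += pd_s
    counts.fn += len(gold_anns) - len(used_gold)
    counts.fp += len(system_anns) - len(used_system)
    return counts


def evaluate_documents(
    gold: BiocCollection,
    system: BiocCollection,
    options: EvalOptions | None = None,
) -> dict[str, EvalCounts]:
    """Per-document fractional counts; raises on structure mismatch."""
    options = options or EvalOptions()
    system_docs = {doc.doc_id: doc for doc in system.documents}
    gold_ids = [doc.doc_id for doc in gold.documents]
    extra = set(system_docs) - set(gold_ids)
    if extra:
        raise EvaluationError(f"system-only documents: {sorted(extra)}")
    per_doc: dict[str, EvalCounts] = {}
    for gold_doc in gold.documents:
        if gold_doc.doc_id not in system_docs:
            raise EvaluationError(f"document {gold_doc.doc_id} missing from system")
        system_doc = system_docs[gold_doc.doc_id]
        if len(gold_doc.passages) != len(system_doc.passages):
            raise EvaluationError(
                f"document {gold_doc.doc_id}: paragraph count differs "
                f"({len(gold_doc.passages)} gold vs {len(system_doc.passages)} system)"
            )
        counts = EvalCounts()
        for k, (gp, sp) in enumerate(zip(gold_doc.passages, system_doc.passages)):
            if gp.offset != sp.offset:
                raise EvaluationError(
                    f"document {gold_doc.doc_id}, paragraph {k}: offsets differ"
                )
            counts += _match_paragraph(gp.annotations, sp.annotations, options)
        per_doc[gold_doc.doc_id] = counts
    return per_doc


def evaluate(
    gold: BiocCollection,
    system: BiocCollection,
    options: EvalOptions | None = None,
) -> tuple[EvalCounts, Scores]:
    """Corpus-level counts and precision/recall/F over all documents."""
    totals = EvalCounts()
    for counts in evaluate_documents(gold, system, options).values():
        totals += counts
    return totals, Scores.from_counts(totals)


def write_report(path, gold, system, options: EvalOptions | None = None) -> None:
    """TSV report with per-document and total TP/FP/FN/P/R/F (3 d.p.)."""
    per_doc = evaluate_documents(gold, system, options)
    totals = EvalCounts()
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("document\tTP\tFP\tFN\tprecision\trecall\tf_measure\n")
        for doc_id, counts in per_doc.items():
            scores = Scores.from_counts(counts)
            handle.write(
                f"{doc_id}\t{counts.tp:.3f}\t{counts.fp:.3f}\t{counts.fn:.3f}\t"
                f"{scores.precision:.3f}\t{scores.recall:.3f}\t{scores.f_measure:.3f}\n"
            )
            totals += counts
        scores = Scores.from_counts(totals)
        handle.write(
            f"TOTAL\t{totals.tp:.3f}\t{totals.fp:.3f}\t{totals.fn:.3f}\t"
            f"{scores.precision:.3f}\t{scores.recall:.3f}\t{scores.f_measure:.3f}\n"
        )
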