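"""Sentence scoring, threshold logic, merging and the entity gate."""

import pytest

from mipassage.bioc import BiocCollection, BiocDocument, BiocPassage
from mipassage.fixtures import FixtureSpec, generate_collection, toy_gazetteers
from mipassage.matching import (
    EntityGate,
    GateConfigError,
    MatchConfig,
    annotate_collection,
    annotate_document,
    entity_gate,
    score_sentence,
    term_in_sentence,
)
from mipassage.preprocess import split_sentences, tokenize
from mipassage.queries import MethodQuery, QueryTable, ScoredTerm


def make_doc(*paragraphs, infon_type="paragraph"):
    passages = []
    offset = 0
    for text in paragraphs:
        passages.append(
            BiocPassage(offset=offset, infons={"type": infon_type}, text=text)
        )
        offset += len(text) + 1
    return BiocDocument("D0", passages)


def query(method_id, *terms):
    return MethodQuery(method_id, list(terms))


name = lambda t: ScoredTerm(t, 1.0, "name")
tier1 = lambda t: ScoredTerm(t, 0.50, "tier1")
tier2 = lambda t: ScoredTerm(t, 0.25, "tier2")
emb = lambda t, s: ScoredTerm(t, s, "embedding")


class TestTermInSentence:
    @pytest.mark.parametrize(
        "term,tokens,expected",
        [
            ("pull down", ["gst", "pull-down", "assay"], True),
            ("pull-down", ["the", "pull", "down", "assay"], True),
            ("y2h", ["y2h", "screen"], True),
            ("two hybrid", ["two", "hybrids"], False),  # no stemming
            ("two hybrid", ["two", "hybrid", "screen"], True),
            ("pull down", ["pulldown"], False),  # fused word is different
            ("yeast two hybrid", ["yeast", "two-hybrid"], True),
        ],
    )
    def test_hyphen_space_unification(self, term, tokens, expected):
        assert term_in_sentence(term, tokens) is expected


class TestScoreSentence:
    def test_name_alone_reaches_threshold(self):
        q = query("MI:0096", name("pull down"))
        tokens = tokenize("a gst pull-down was performed today .")
        config = MatchConfig.for_mode("baseline")
        assert score_sentence(tokens, q, config) >= 1.0

    def test_tier_combination_reaches_exactly_one(self):
        q = query("MI:0096", name("pull down"), tier1("gst"),
                  tier2("beads"), tier2("glutathione"))
        tokens = tokenize("gst beads with glutathione were used .")
        config = MatchConfig.for_mode("tfrf")
        assert score_sentence(tokens, q, config) == pytest.approx(1.0)

    def test_repeated_term_counts_once(self):
        q = query("MI:0096", tier1("gst"))
        tokens = tokenize("gst gst gst")
        config = MatchConfig.for_mode("tfrf")
        assert score_sentence(tokens, q, config) == pytest.approx(0.50)

    def test_maximum_aggregation_takes_best_cosine(self):
        q = query("MI:0018", emb("yeast two-hybrid", 0.91416), emb("y2h assay", 0.845))
        tokens = tokenize("a yeast two-hybrid and y2h assay study .")
        config = MatchConfig.for_mode("embedding")
        assert score_sentence(tokens, q, config) == pytest.approx(0.91416)
        assert score_sentence(tokens, q, config) >= config.main_threshold

    def test_no_match_scores_zero(self):
        q = query("MI:0018", name("two hybrid"))
        assert score_sentence(tokenize("nothing relevant here ."), q,
                              MatchConfig()) == 0.0


class TestMatchConfig:
    def test_mode_defaults(self):
        base = MatchConfig.for_mode("baseline")
        assert (base.main_threshold, base.neighbor_threshold) == (1.0, 0.5)
        assert base.aggregation == "additive"
        embedding = MatchConfig.for_mode("embedding")
        assert (embedding.main_threshold, embedding.neighbor_threshold) == (0.9, 0.65)
        assert embedding.aggregation == "maximum"

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            MatchConfig(main_threshold=0.5, neighbor_threshold=0.9)


class TestAnnotateDocument:
    def test_single_seed_sentence_annotated(self):
        doc = make_doc(
            "filler words only in this sentence . "
            "a pull down experiment was done here . "
            "more filler words close the paragraph ."
        )
        table = QueryTable({"MI:0096": query("MI:0096", name("pull down"))})
        out = annotate_document(doc, table, MatchConfig.for_mode("baseline"))
        anns = list(out.annotations())
        assert len(anns) == 1
        ann = anns[0]
        assert ann.infons == {"type": "ExperimentalMethod", "PSIMI": "0096"}
        assert ann.text == "a pull down experiment was done here ."
        passage = out.passages[0]
        local = ann.offset - passage.offset
        assert passage.text[local : local + ann.length] == ann.text

    def test_neighbor_with_tier1_term_merges(self):
        doc = make_doc(
            "a pull down experiment was done here . "
            "the gst beads were then washed twice ."
        )
        table = QueryTable({
            "MI:0096": query("MI:0096", name("pull down"), tier1("gst")),
        })
        out = annotate_document(doc, table, MatchConfig.for_mode("tfrf"))
        anns = list(out.annotations())
        assert len(anns) == 1
        assert anns[0].text == (
            "a pull down experiment was done here . "
            "the gst beads were then washed twice ."
        )

    def test_neighbor_below_threshold_not_merged(self):
        doc = make_doc(
            "a pull down experiment was done here . "
            "the beads were then washed twice today ."
        )
        table = QueryTable({
            "MI:0096": query("MI:0096", name("pull down"), tier2("beads")),
        })
        out = annotate_document(doc, table, MatchConfig.for_mode("tfrf"))
        anns = list(out.annotations())
        assert len(anns) == 1
        assert anns[0].text == "a pull down experiment was done here ."

    def test_no_match_returns_document_unchanged(self):
        doc = make_doc("entirely unrelated prose fills this paragraph today .")
        table = QueryTable({"MI:0096": query("MI:0096", name("pull down"))})
        out = annotate_document(doc, table, MatchConfig())
        assert out == doc

    def test_ineligible_paragraphs_untouched(self):
        doc = make_doc("a pull down experiment was done here .",
                       infon_type="table")
        table = QueryTable({"MI:0096": query("MI:0096", name("pull down"))})
        out = annotate_document(doc, table, MatchConfig())
        assert list(out.annotations()) == []

    def test_multi_label_baseline_annotates_both_methods(self):
        doc = make_doc(
            "both pull down and two hybrid data appear in this one sentence ."
        )
        table = QueryTable({
            "MI:0096": query("MI:0096", name("pull down")),
            "MI:0018": query("MI:0018", name("two hybrid")),
        })
        out = annotate_document(doc, table,
                                MatchConfig.for_mode("baseline"))
        assert sorted(a.infons["PSIMI"] for a in out.annotations()) == [
            "0018", "0096",
        ]
        single = annotate_document(
            doc, table,
            MatchConfig.for_mode("baseline", multi_label_baseline=False),
        )
        # tie broken toward the smallest PSI-MI id
        assert [a.infons["PSIMI"] for a in single.annotations()] == ["0018"]

    def test_merging_is_maximal_per_method(self, fixture_pair, baseline_table):
        _, bare = fixture_pair
        out = annotate_collection(bare, baseline_table,
                                  MatchConfig.for_mode("baseline"))
        for doc in out.documents:
            for passage in doc.passages:
                by_method = {}
                for ann in passage.annotations:
                    by_method.setdefault(ann.infons["PSIMI"], []).append(ann)
                for anns in by_method.values():
                    anns.sort(key=lambda a: a.offset)
                    for a, b in zip(anns, anns[1:]):
                        gap = passage.text[a.end - passage.offset
                                           : b.offset - passage.offset]
                        assert gap.strip(), "adjacent same-method annotations"

    def test_lowering_main_threshold_never_removes_coverage(self):
        doc = make_doc(
            "gst beads were used in this experiment . "
            "a pull down experiment was done here . "
            "unrelated filler closes the paragraph today ."
        )
        table = QueryTable({
            "MI:0096": query("MI:0096", name("pull down"), tier1("gst")),
        })
        def coverage(config):
            out = annotate_document(doc, table, config)
            covered = set()
            for ann in out.annotations():
                covered.update(range(ann.offset, ann.end))
            return covered
        high = coverage(MatchConfig.for_mode("tfrf"))
        low = coverage(MatchConfig.for_mode("tfrf", main_threshold=0.5,
                                            neighbor_threshold=0.5))
        assert high <= low


def brute_force_baseline(collection, table):
    """Independent oracle: scan every sentence for every name, merge runs."""
    results = {}
    for doc in collection.documents:
        spans = []
        for passage in doc.passages:
            if passage.infons.get("type") in {"title", "table caption", "table",
                                              "ref", "footnote", "front"}:
                continue
            if len(passage.text.split()) < 5:
                continue
            sentences = split_sentences(passage.text, passage.offset)
            for q in table:
                flagged = [
                    any(term_in_sentence(t.term, tokenize(s.text))
                        for t in q.terms)
                    for s in sentences
                ]
                i = 0
                while i < len(sentences):
                    if flagged[i]:
                        j = i
                        while j + 1 < len(sentences) and flagged[j + 1]:
                            j += 1
                        spans.append(
                            (q.method_id.split(":")[-1],
                             sentences[i].offset, sentences[j].end)
                        )
                        i = j + 1
                    else:
                        i += 1
        results[doc.doc_id] = sorted(spans)
    return results


class TestBaselineOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_sentence_brute_force(self, seed, lexicon, baseline_table):
        spec = FixtureSpec(seed=seed, n_documents=2, paragraphs_per_doc=6,
                           decoy_infon_fraction=0.4, layout_paragraphs=1)
        _, bare = generate_collection(spec, lexicon)
        out = annotate_collection(bare, baseline_table,
                                  MatchConfig.for_mode("baseline"))
        got = {
            doc.doc_id: sorted(
                (a.infons["PSIMI"], a.offset, a.end) for a in doc.annotations()
            )
            for doc in out.documents
        }
        assert got == brute_force_baseline(bare, baseline_table)


class TestEntityGate:
    def test_protein_and_keyword_required(self):
        proteins = {"tbk1", "ddx3x"}
        keywords = {"interacts"}
        assert entity_gate("TBK1 interacts with DDX3X", proteins, keywords)
        assert not entity_gate("TBK1 was purified", proteins, keywords)
        assert not entity_gate("they interact strongly; interacts shown",
                               proteins, keywords)

    def test_empty_gazetteer_is_config_error(self):
        with pytest.raises(GateConfigError):
            entity_gate("text", set(), {"interacts"})

    def test_gate_enabled_without_gazetteers_fails(self, fixture_pair,
                                                   baseline_table):
        _, bare = fixture_pair
        with pytest.raises(GateConfigError):
            annotate_collection(bare, baseline_table,
                                MatchConfig(gate_enabled=True))

    def test_gated_annotations_are_subset(self, lexicon, baseline_table):
        spec = FixtureSpec(seed=21, layout_paragraphs=2, paragraphs_per_doc=7)
        _, bare = generate_collection(spec, lexicon)
        proteins, keywords = toy_gazetteers()
        gate = EntityGate(set(proteins), set(keywords))
        config = MatchConfig.for_mode("baseline")
        without = annotate_collection(bare, baseline_table, config)
        with_gate = annotate_collection(bare, baseline_table,
                                        config.with_gate(), gate)
        def spans(collection):
            return {
                (doc.doc_id, a.infons["PSIMI"], a.offset, a.length)
                for doc in collection.documents for a in doc.annotations()
            }
        assert spans(with_gate) <= spans(without)
        # the layout paragraphs guarantee the gate actually removes something
        assert spans(with_gate) < spans(without)
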