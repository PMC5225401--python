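# Methods

This note documents the retrieval model, its parameters, the numerical and
design choices made where the behaviour was genuinely open, what the
synthetic fixtures do and do not emulate, and known limitations.

## Problem and data model

The task is passage-level retrieval: locate the sequences of sentences in a
full-text article that describe an experimental interaction detection
method (PSI-MI ontology, subtree `MI:0045`) used as evidence for a physical
protein–protein interaction, and annotate them in place. Articles are BioC
XML collections; annotations are stand-off spans with two infons, `type`
(always `ExperimentalMethod`) and `PSIMI` (the 4-digit local method id).
Offsets are 0-based code-point offsets into the document text as stored in
the XML; lengths are code-point counts. Annotation ids are document-scoped
rendered integers incrementing by one; the base is 0 (the convention is not
fixed by the format, so the counter start is an argument). A passage
annotated for several methods carries one annotation per method; annotations
never cross paragraph boundaries.

## Preprocessing

Paragraph eligibility: passages with infon types `title`, `table caption`,
`table`, `ref`, `footnote`, `front` are skipped, as are passages with fewer
than 5 whitespace-delimited words (short "paragraphs" are usually
mis-tagged headers). Both the excluded set and the minimum are
configurable, since BioC conversions vary; a passage lacking a `type` infon
is treated as eligible and logged rather than silently dropped.

Sentence splitting is rule-based: a boundary after every period followed by
whitespace. The rule deliberately over-splits abbreviations ("e.g." ends a
sentence); this is accepted because the matcher needs exact, reproducible
character offsets more than linguistic accuracy, and neighbour extension
reattaches split fragments in practice. Any whitespace after the period
counts as a boundary (a strict-space variant is available); splitting is
period-only — `?`/`!` do not end sentences, matching the scientific-prose
register where they are rare.

Tokenization lowercases, removes punctuation/braces/parentheses/brackets by
replacement with spaces, and drops purely numeric tokens (digits and float
fragments). Intra-word hyphens are preserved: query terms such as
`pull-down`, `two-hybrid` and alphanumerics like `y2h` must stay matchable.
The tokenizer is idempotent on its own space-joined output.

## Queries and matching

The baseline query of a method is its ontology name list (canonical name +
synonyms), normalized to lowercase, each with weight 1.0. Term matching is
a contiguous token-subsequence test with hyphen/space unification on both
sides (`pull down` matches the token `pull-down` and vice versa); there is
no stemming.

Sentence scoring sums the weights of the *distinct* matched terms
(additive aggregation) or takes the maximum matched weight. Defaults by
query type:

| mode      | main threshold | neighbour threshold | aggregation |
|-----------|----------------|---------------------|-------------|
| baseline  | 1.0            | 0.5                 | additive    |
| tf.rf     | 1.0            | 0.5                 | additive    |
| embedding | 0.9            | 0.65                | maximum     |

All comparisons are ≥. The additive rule reproduces the tier arithmetic
(0.50 + 0.25 + 0.25 = 1.0); for embedding queries the stated thresholds read
as per-term cosine comparisons, so maximum aggregation is the default there
— the aggregation is configurable in every mode because the combination rule
for cosine weights is not pinned down by the tier arithmetic. A sentence
whose top method reaches the main threshold is a seed; in baseline mode
every name-matched method seeds by default (`multi_label_baseline`), since a
name match alone is decisive there. Seed ties across methods in
single-label scoring go to the numerically smallest PSI-MI id (an arbitrary
but deterministic rule).

Neighbour extension is one step: the immediate previous/next sentence of a
seed joins when its own best-scoring method is the same and reaches the
neighbour threshold. Chains of seeds still merge, because merging collects
*maximal runs* of consecutive same-method sentences into one annotation
whose span covers the run. The optional entity gate is applied to the
merged candidate passage (not per sentence), after merging and before
emission: the passage must contain at least one protein gazetteer term and
one interaction keyword. The gate stands in for a named-entity tagger; it
is gazetteer-based by design and the packaged keyword list is a small
hand-written synthetic stand-in (`interaction_keywords_synthetic.txt`) — a
deployment should supply its own protein list and an ontology-derived
keyword list.

## tf.rf expansion

Counting is over the texts under gold annotation tags, tokenized as above,
unigram only. A passage annotated with several methods is positive for each
of its own methods and negative for all others. Ranking ties break
lexicographically. Name exclusion from the tiers is exact-string: a token
is removed only when it equals a (single-word) name, so hyphenated variants
of multi-word names (`pull-down` for `pull down`) legitimately appear as
tier terms. Tier weights 0.50/0.25 and the 1.0 threshold are fixed
heuristic constants, not tuned. The `f7s7` and `f10s10` configurations take
the first 7/next 7 and first 10/next 10 surviving tokens; manual tier lists
can be supplied in the same shape.

## Embedding expansion

Embeddings are consumed in word2vec text format (`vocab dim` header;
phrases as underscore-joined tokens, converted to spaces at load). Cosines
are computed on raw vectors with a zero-vector guard (similarity 0).
Out-of-vocabulary initial terms contribute nothing; a method with no
in-vocabulary initial terms keeps its baseline query (logged). Training
embeddings is out of scope — the store is an input.

Before expansion, known-ambiguous initial terms are removed from their
queries entirely (they neither expand nor match); the packaged default list
has 15 (method, term) pairs of short/polysemous synonyms such as
(`MI:0018`, `2h`) and (`MI:0676`, `tap`).

The pipeline order is fixed: per-method **combine**, one global **clean**
pass, per-method **filter**. Combine keeps the highest cosine per distinct
term, then drops terms equal to any method's name. Clean drops a term from
method M when it contains another method's name as a whitespace/hyphen-
delimited word sub-phrase (so `gst-pull-down-assay` contains `pull down`),
or when another method's list holds it with a *strictly* higher cosine;
score ties keep the term in both lists and are logged, so the
"each term in at most one list" property holds only for tie-free inputs —
with real-valued cosines ties are negligible. Both clean rules are
evaluated against the input snapshot, not incrementally. Filter removes a
term when another list entry is a character substring of it with a higher
score; a word-boundary variant is available (character semantics reproduce
the documented behaviour and are the default). A dedicated test pins the
pipeline order by exhibiting a fixture on which reordering changes the
output.

## Evaluation

Documents are aligned by id and paragraphs positionally (offsets checked);
any structural mismatch is an error naming the document/paragraph. Two
annotations can match when their (possibly remapped) method ids agree — or
unconditionally in id-agnostic mode — and their texts share at least one
character of common substring. "Common text" is tested on the annotation
strings, per the character-string framing of the metric. The intersection
is the shorter text under containment, else the longest common substring
(computed with `difflib.SequenceMatcher`, `autojunk=False`; ties resolve to
the earliest occurrence in the gold text, which is inert since only the
length feeds the metric).

When several same-method annotations overlap in one paragraph, pairing is
greedy by descending Jaccard, one-to-one (the resolution of many-to-many
overlaps is not otherwise determined). Each matched pair adds J to TP,
pdJM to FN and pdJS to FP — both partial distances are always added; each
is zero when its side is fully covered, and the two-sided formula also
handles partial overlaps where both sides have uncovered text. Unmatched
gold/system annotations add 1.0 to FN/FP respectively, which subsumes the
gold-only-paragraph and system-only-paragraph cases. P or R with a zero
denominator is reported as 0 and logged. Accumulation is in full float
precision; reports round to 3 decimals.

The `coip` variant remaps ids 0006 and 0007 (anti bait / anti tag
coimmunoprecipitation) to their parent 0019 on both sides before matching;
the id-agnostic variant ignores ids altogether.

## Synthetic fixtures

`fixtures.generate_collection` plants method passages in filler prose built
from a closed 24-word vocabulary disjoint from all method/protein/keyword
terms, so every match is intentional. Planted sentences carry the chosen
method term variant plus one protein and one interaction keyword (so the
gate never rejects true positives); decoy paragraphs carry excluded infon
types or fewer than five words; optional "layout" paragraphs mention a
method name without protein/keyword — the false-positive shape the gate
suppresses. Default scale is 2 documents × 5 paragraphs with 3 plantings:
large enough to exercise merging, decoys and multi-document evaluation,
small enough that the whole suite runs in seconds. One `random.Random(seed)`
stream per fixture makes output byte-identical across runs.

`fixtures.generate_embeddings` places each cluster's members inside a cone
around a cluster-specific orthogonal axis, with the cone half-angle set to
0.8 × ½·arccos(target) so all intra-cluster cosines provably exceed the
target (default 0.95, comfortably above the 0.9 matching threshold);
magnitudes vary in [0.5, 2] to exercise the raw-cosine path. The generator
re-verifies both guarantees numerically and refuses infeasible specs.

What the fixtures do **not** emulate: real scientific prose (paraphrase,
anaphora, nested clauses), noisy BioC conversions, realistic embedding
geometry (real neighbourhoods are far less separable than orthogonal
clusters), and class imbalance across 100+ methods. Passing the end-to-end
recovery tests therefore demonstrates the machinery is correct — exact
spans, thresholds, merging, pipeline order — not that the same thresholds
achieve any particular score on real articles.

## Numerical choices and degenerate inputs

- Jaccard of two empty passages is defined as 0 and logged.
- `tf.rf` guards division by zero with `max(1, c)`.
- Threshold comparisons are ≥ throughout.
- Ranking and neighbour ties break lexicographically; seed-method ties by
  smallest id; all outputs are deterministic functions of (inputs, seed).
- Scores in reports are rounded to 3 decimals; internal accumulation is
  unrounded.

## Limitations

- The gate is a gazetteer stand-in for proper protein NER; precision gains
  depend entirely on gazetteer quality.
- Sibling methods with near-identical vocabularies (e.g. the
  coimmunoprecipitation subtypes 0006/0007 vs 0019) are not distinguished;
  the `coip` evaluation variant exists precisely to measure that effect.
- Corpus-scale scores on real article sets require the external gold
  corpus and full-corpus embeddings, which are inputs, not artifacts of
  this package.
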