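# mipassage

Passage retrieval for **experimental protein–protein interaction (PPI)
detection methods** in full-text biomedical articles.

Biocurators who populate interaction databases need to know not just *that*
two proteins interact but *which experiment* (two hybrid, pull down,
coimmunoprecipitation, ...) produced the evidence. Those details live in
passages — sequences of sentences — of full-text articles. `mipassage`
retrieves and annotates such passages in [BioC](http://bioc.sourceforge.net/)
XML collections, using the experimental interaction detection methods of the
PSI-MI ontology (the subtree under `MI:0045`) as its target vocabulary.

## What it does

1. **Baseline query matching.** Each method's initial query is its ontology
   name list (weight 1.0 each). A sentence containing a name is annotated
   with that method; consecutive same-method sentences merge into one
   passage annotation with exact character offsets.

2. **Supervised expansion (tf.rf).** From gold-annotated passages, each
   token is weighted with term frequency × relevance frequency,

   ```
   tf.rf = tf · log2(2 + a / max(1, c))
   ```

   where `tf` counts the token in the method's own (positive) passages, `a`
   counts positive passages containing it and `c` negative passages
   containing it. Top-ranked tokens (names excluded) form Tier 1 (weight
   0.50) and Tier 2 (weight 0.25) lists; a sentence is annotated when its
   additive score reaches 1.0 — a name alone, one Tier 1 + two Tier 2 terms,
   two Tier 1 terms, or four Tier 2 terms.

3. **Unsupervised expansion (word embeddings).** Initial terms are looked up
   in a word2vec-format embedding store; the top-100 cosine neighbours per
   term are pooled and reduced by **combine** (deduplicate, drop ontology
   names), **clean** (cross-method: drop terms containing another method's
   name or scored higher in another method's list) and **filter** (drop
   terms that have a higher-scoring substring). Survivors join the query
   with their cosine scores; matching uses thresholds 0.9 (seed sentence)
   and 0.65 (neighbouring sentences).

4. **Entity gate.** Optionally, a candidate passage must mention at least
   one protein name and one interaction keyword (gazetteer-based) — this
   trades a little recall for precision.

5. **Partial-Jaccard evaluation.** System output is scored against gold
   annotations per paragraph. A matched pair of passages M (gold) and S
   (system), intersected by containment or longest common substring,
   contributes

   ```
   J    = |M ∩ S| / |M ∪ S|        → TP
   pdJM = |M| / |M ∪ S| − J        → FN   (gold text the system missed)
   pdJS = |S| / |M ∪ S| − J        → FP   (system text beyond the gold span)
   ```

   with `pdJM + pdJS = 1 − J`. Unmatched annotations count 1.0 to FN or FP.
   Precision, recall and F-measure follow from the fractional totals.

## Worked example

```bash
python examples/passage_evaluation.py
```

```
gold inside system   |M|= 371 |S|= 523 J=0.709  pdJM=0.000  pdJS=0.291
system inside gold   |M|= 452 |S|= 258 J=0.571  pdJM=0.429  pdJS=0.000
exact match          |M|= 120 |S|= 120 J=1.000  pdJM=0.000  pdJS=0.000

totals: TP=2.280  FP=0.291  FN=0.429
```

The first system passage covered the whole 371-character gold passage but
included an extra sentence (523 characters total): TP gains the Jaccard
index 371/523 = 0.709 and FP gains the system-side remainder 0.291. The
second system passage found only 258 of 452 gold characters: FN gains
0.429. The exact match adds a full 1.0 to TP.

```bash
python examples/embedding_expansion.py
```

```
baseline   precision=1.000 recall=0.333 F=0.500
embedding  precision=1.000 recall=1.000 F=1.000
```

Passages planted with cluster synonyms (`split-ubiquitin`,
`interaction-trap`) are invisible to name matching but retrieved once the
queries are expanded with their high-cosine neighbours.

The other examples (`baseline_annotation.py`, `tfrf_expansion.py`) show
exact-span recovery of name plantings and tf.rf tier construction.

## Command line

```bash
mipassage simulate --seed 7 --out fix/          # synthetic corpus + resources
mipassage expand   --mode embedding --lexicon fix/lexicon.tsv \
                   --vectors fix/vectors.txt --out table.tsv
mipassage annotate --in fix/bare.xml --out out.xml \
                   --query-table table.tsv --mode embedding
mipassage evaluate --gold fix/gold.xml --system out.xml --report report.tsv
```

## Layout

```
src/mipassage/      bioc, preprocess, queries, tfrf, embeddings,
                    matching, evaluation, fixtures, cli
src/mipassage/data/ packaged lexicon, ambiguous-term removals,
                    synthetic interaction-keyword list
examples/           one narrative script per capability
tests/              pytest suite (unit + property + end-to-end)
docs/methods.md     models, parameters, design choices, limitations
```
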