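"""Learn tf.rf expansion terms from gold-annotated passages.

Ranks the tokens of each method's annotated passages by
tf * log2(2 + a / max(1, c)) — frequency in the method's own passages
relative to other methods' passages — and builds the automatic
Tier 1 / Tier 2 lists (weights 0.50 / 0.25, first 7 / next 7 tokens,
names excluded).
"""

from mipassage.fixtures import FixtureSpec, generate_collection, toy_lexicon
from mipassage.tfrf import build_tier_lists, rank_terms

lexicon = toy_lexicon()
gold, _ = generate_collection(FixtureSpec(seed=13), lexicon)

for method_id in ("MI:0096", "MI:0018"):
    ranked = rank_terms(gold, method_id)
    print(f"\n{method_id} — top tokens by tf.rf weight:")
    for token, weight in ranked[:5]:
        print(f"  {token:<15} {weight:.3f}")
    tiers = build_tier_lists(ranked, lexicon.names(method_id), k1=7, k2=7)
    print("  Tier 1 (0.50):", [t.term for t in tiers.tier1])
    print("  Tier 2 (0.25):", [t.term for t in tiers.tier2])
# High-weight tokens are those concentrated in the method's own
# passages; ontology names never appear in the tiers.
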