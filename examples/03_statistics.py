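"""Functional-category enrichment and the enriched-vs-non-enriched rank test.

First a small exact hypergeometric example: 10 background genes, 5 in
category C, 4 targets all in C — the upper-tail p is 5/210.  Then a
Kruskal-Wallis comparison of interaction-prediction ranks between
enriched and non-enriched peaks (lower rank = stronger predicted
interaction), using the exact permutation null because the pooled sample
is small.
"""

import crafdseq as cs

background = {f"g{i}": {"C"} if i < 5 else {"D"} for i in range(10)}
for r in cs.category_enrichment({"g0", "g1", "g2", "g3"}, background):
    print(f"category {r.category}: {r.k_targets_in_cat}/{r.n_targets} targets vs "
          f"{r.k_background_in_cat}/{r.n_background} background, "
          f"p = {r.p_value:.5f} (BH-adjusted {r.adjusted_p:.5f})")

# Enriched peaks carry better (smaller) predicted-interaction ranks.
table = [
    (1, "enriched", 3), (2, "enriched", 11), (3, "enriched", 8),
    (4, "enriched", 25), (5, "not_enriched", 140), (6, "not_enriched", 310),
    (7, "not_enriched", 95), (8, "not_enriched", 220),
]
rc = cs.compare_enriched_ranks(table)
print(f"\nKruskal-Wallis H = {rc.H:.3f}, p = {rc.p_value:.4f} ({rc.method})")
print(f"median rank: enriched {rc.median_enriched:.0f} vs "
      f"non-enriched {rc.median_non_enriched:.0f} -> {rc.direction}")
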