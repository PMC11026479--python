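"""Gene-set enrichment of the top-ranked variants' host genes.

Ranks variants by effect magnitude, then asks whether a gene-set term is
over-represented among the top genes relative to thousands of size-matched
control gene sets (with optional length/GC matching).
"""

import numpy as np
import pandas as pd

from utrscreen.enrich import (
    load_term_map, permutation_enrichment, rank_top_variants, sample_controls,
)

rng = np.random.default_rng(3)

# A background universe of 1,000 genes; term "growth" covers 15% of it.
background = [f"GENE{i:04d}" for i in range(1000)]
growth = set(rng.choice(background, size=150, replace=False))
term_map = load_term_map(
    [(g, "growth") for g in growth]
    + [(g, "other") for g in rng.choice(background, size=200, replace=False)]
)

# Simulated calls: 120 variants; variants in "growth" genes get larger
# effects, so the term should surface among the top genes.
genes = list(rng.choice(background, size=120, replace=False))
lnfc = np.where(
    [g in growth for g in genes],
    rng.normal(0.8, 0.2, size=120),
    rng.normal(0.2, 0.2, size=120),
)
calls = pd.DataFrame({
    "variant_id": [f"v{i}" for i in range(120)],
    "lnFC": lnfc,
    "gene": genes,
})

top = rank_top_variants(calls, top_n=40)
query = list(top.gene)
print(f"query: host genes of the top {len(top)} variants by |lnFC|")

controls = sample_controls(query, background, n_sets=2000, seed=7)
result = permutation_enrichment(query, controls, term_map)
print(result.round(4).to_string(index=False))

sig = result[result.significant]
print(f"\nsignificant terms (FDR < 0.05, occurrence >= 5): "
      f"{list(sig.term)}")
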