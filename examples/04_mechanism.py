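"""Mechanistic follow-up on called variants.

Builds up/down sequence groups around functional variants, looks for
over-represented hexamers, and scores how an AU-rich-element PWM changes
between alleles relative to shuffled-PWM and nonfunctional-variant nulls.
"""

import numpy as np

from utrscreen import quantify, simulate
from utrscreen.motifs import (
    PWM, build_sequence_groups, hexamer_enrichment, motif_strength_null,
)

cfg = simulate.SimConfig(seed=5, n_variants=150, frac_functional=0.3)
_, _, truth, oligos = simulate.build_library(cfg)
counts = simulate.simulate_counts(oligos, truth, cfg)
calls = quantify.quantify_screen(counts, oligos)

up, down = build_sequence_groups(calls, oligos, flank=5)
print(f"sequence groups: {len(up)} up-regulating, {len(down)} down-regulating "
      "windows (higher- vs lower-expressed allele)")

hex_table = hexamer_enrichment(up, down)
print("\ntop hexamers over-represented in the up group:")
print(hex_table[["hexamer", "fg_count", "bg_count", "p_value", "fdr"]]
      .head(3).to_string(index=False))

# An AU-rich element-like PWM (AUUUA core with soft shoulders).
are = PWM(matrix=(
    (0.85, 0.05, 0.05, 0.05),
    (0.05, 0.05, 0.05, 0.85),
    (0.05, 0.05, 0.05, 0.85),
    (0.05, 0.05, 0.05, 0.85),
    (0.85, 0.05, 0.05, 0.05),
), name="ARE")

func = calls[calls.functional].variant_id
nonfunc = calls[~calls.functional].variant_id
ins = oligos.set_index(["variant_id", "allele"])["insert_sequence"]
off = int(oligos.variant_offset.iloc[0]) - len(are) // 2

pairs = lambda vids: [(ins[(v, "ref")], ins[(v, "alt")]) for v in vids]
null_table = motif_strength_null(
    pairs(func), are, pairs(nonfunc),
    offsets_functional=[off] * len(func),
    offsets_nonfunctional=[off] * len(nonfunc),
    seed=0,
)
print("\nARE strength-change (|S_var - S_ref|) of functional variants "
      "against two nulls (KS):")
print(null_table.round(4).to_string(index=False))
print("\n(on random sequence the functional set matches its nulls, "
      "as expected: the simulator plants no motifs)")
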