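"""Design a synthesis oligo library from a variant table and 3' UTR BED.

Walks the design stages one by one: annotate variants with UTR intervals,
apply the rare-variant frequency filter, screen inserts for cloning-
incompatible substrings, and assemble the final 200-nt ref/alt oligo pairs.
"""

import numpy as np
import pandas as pd

from utrscreen.design import (
    DESIGN2, assemble_oligo, extract_utr_variants, filter_rare_variants,
    oligos_to_frame, read_bed, screen_sequences,
)

rng = np.random.default_rng(0)

# A toy genome: one 600-nt contig whose 3' UTR spans positions 100-500.
genome = {"chr1": "".join(rng.choice(list("ACGT"), size=600))}
utr = read_bed(["chr1\t100\t500\tGENE1\t0\t+"])

# Candidate variants: some inside the UTR, some rare, one indel.
positions = [150, 250, 300, 350, 450, 550]
variants = pd.DataFrame(
    {
        "variant_id": [f"v{i}" for i in range(len(positions))],
        "chrom": "chr1",
        "pos": positions,
        "ref": [genome["chr1"][p - 1] for p in positions],
        "alt": ["C" if genome["chr1"][p - 1] != "C" else "G" for p in positions[:-1]]
        + ["CT"],  # the last one is an insertion and will be filtered
        "adjAF": [0.001, 0.5, 0.004, 0.0001, 0.009, 0.002],
        "gene": "",
        "sources": "gnomad",
        "cosmic_cnt": 0,
        "driver_role": "none",
        "strand": "+",
    }
)

in_utr = extract_utr_variants(variants, utr)
print(f"in 3' UTR: {len(in_utr)} of {len(variants)} variants")

rare = filter_rare_variants(in_utr, max_af=0.01)
print(f"rare SNVs (adjAF < 0.01): {list(rare.variant_id)}")

oligos = []
for _, var in rare.iterrows():
    oligos.extend(assemble_oligo(var, genome, DESIGN2))
table = oligos_to_frame(oligos, DESIGN2)

passed, failures = screen_sequences(
    dict(zip(table.oligo_id, table.insert_sequence))
)
print(f"cloning screen: {len(passed)} inserts pass, {len(failures)} rejected")

print("\nfinal library:")
print(table[["oligo_id", "allele", "variant_offset"]].to_string(index=False))
print(f"\nall oligos are {table.full_sequence.str.len().unique()[0]} nt; "
      f"the variant sits at insert offset {DESIGN2.variant_offset}")
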