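"""Oligo library design for a 3' UTR reporter screen.

Selects single-nucleotide variants falling in annotated 3' UTRs, filters them
by population frequency (or somatic recurrence), and assembles synthesis-ready
200-nt oligos in which the tested UTR window is centered on the variant and
flanked by cloning segments (subpool primers and restriction sites).

Coordinate conventions: genomic variant positions are 1-based (VCF); interval
inputs are 0-based half-open (BED); all offsets inside designed sequences are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .seq import revcomp, complement

# Restriction sites used for cloning.
ECORI = "GAATTC"
BAMHI = "GGATCC"

# Default adaptor sequences.  These are placeholders with the documented
# lengths (user-supplied in a real synthesis run); they are screened to be
# free of the restriction sites above.
DEFAULT_FWD_SUBPOOL = "AGTCCTGACGTCTAT"        # 15 nt
DEFAULT_REV_SUBPOOL = "CTGAGTCGTGCAGAC"        # 15 nt
DEFAULT_FWD_MOTIF = "AGGCACTTGCATGACTACGTT"    # 21 nt (motif-mutagenesis pool)


@dataclass(frozen=True)
class OligoLayout:
    """Segment layout of a 200-nt synthesis oligo.

    ``design1``: fwd subpool primer (15) + EcoRI + 158-nt insert + BamHI +
    rev subpool primer (15).  ``design2``: fwd subpool primer (15) + EcoRI +
    164-nt insert + rev subpool primer (15).  ``motif``: 21-nt forward primer
    + EcoRI + 158-nt insert + rev primer (15), used for saturation panels.
    """

    name: str
    insert_len: int
    fwd_primer: str = DEFAULT_FWD_SUBPOOL
    rev_primer: str = DEFAULT_REV_SUBPOOL
    has_bamhi: bool = False
    total_len: int = 200

    def __post_init__(self) -> None:
        if self.segment_sum != self.total_len:
            raise ValueError(
                f"layout {self.name!r}: segments sum to {self.segment_sum}, "
                f"expected {self.total_len}"
            )

    @property
    def segment_sum(self) -> int:
        n = len(self.fwd_primer) + len(ECORI) + self.insert_len + len(self.rev_primer)
        if self.has_bamhi:
            n += len(BAMHI)
        return n

    @property
    def insert_start(self) -> int:
        """0-based start of the insert within the full oligo."""
        return len(self.fwd_primer) + len(ECORI)

    @property
    def variant_offset(self) -> int:
        """0-based offset of the variant base within the insert (centered)."""
        return (self.insert_len - 1) // 2

    def assemble(self, insert: str) -> str:
        if len(insert) != self.insert_len:
            raise ValueError(
                f"insert length {len(insert)} != layout insert_len {self.insert_len}"
            )
        tail = BAMHI + self.rev_primer if self.has_bamhi else self.rev_primer
        return self.fwd_primer + ECORI + insert + tail


DESIGN1 = OligoLayout(name="design1", insert_len=158, has_bamhi=True)
DESIGN2 = OligoLayout(name="design2", insert_len=164)
MOTIF_LAYOUT = OligoLayout(
    name="motif", insert_len=158, fwd_primer=DEFAULT_FWD_MOTIF
)

LAYOUTS = {"design1": DESIGN1, "design2": DESIGN2, "motif": MOTIF_LAYOUT}

#: forbidden substrings screened out of inserts (both strands)
DEFAULT_FORBIDDEN = (ECORI, BAMHI, DEFAULT_FWD_SUBPOOL, DEFAULT_REV_SUBPOOL)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MotifSpec:
    """A known cis-regulatory element to mutagenize exhaustively."""

    motif_id: str
    motif_sequence: str
    host_gene: str = ""
    flank_up: int = 22
    flank_down: int = 23

    def __post_init__(self) -> None:
        for f in (self.flank_up, self.flank_down):
            if not 0 <= f:
                raise ValueError("flanks must be non-negative")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "adjAF", "gene",
    "sources", "cosmic_cnt", "driver_role", "strand",
]


def read_bed(path_or_lines) -> pd.DataFrame:
    """Parse a BED file of 3' UTR intervals (chrom, start, end[, name, score,
    strand]).  Raises ``ValueError`` naming the offending line number."""
    if isinstance(path_or_lines, (str, bytes)):
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    else:
        lines = list(path_or_lines)
    rows = []
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line {i}: fewer than 3 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"malformed BED line {i}: non-integer coordinate") from exc
        if end < start:
            raise ValueError(f"malformed BED line {i}: end < start")
        rows.append(
            {
                "chrom": parts[0],
                "start": start,
                "end": end,
                "name": parts[3] if len(parts) > 3 else "",
                "strand": parts[5] if len(parts) > 5 else "+",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def extract_utr_variants(variants: pd.DataFrame, utr_intervals: pd.DataFrame) -> pd.DataFrame:
    """Keep variants whose 1-based ``pos`` falls in a 3' UTR interval.

    ``utr_intervals`` uses BED convention (0-based half-open), so a variant is
    retained iff ``pos - 1`` lies in ``[start, end)`` of some interval.  Gene
    and strand are annotated from the first overlapping interval (alternative
    overlaps are counted in the ``n_overlaps`` column).
    """
    trees: dict[str, IntervalTree] = {}
    meta: dict[str, list] = {}
    for chrom, grp in utr_intervals.groupby("chrom"):
        tree = IntervalTree()
        for idx, row in grp.iterrows():
            if row.end > row.start:
                tree.addi(row.start, row.end, idx)
        trees[chrom] = tree

    keep_rows = []
    for _, var in variants.iterrows():
        tree = trees.get(var.chrom)
        if tree is None:
            continue
        hits = sorted(tree[var.pos - 1], key=lambda iv: iv.data)
        if not hits:
            continue
        first = utr_intervals.loc[hits[0].data]
        row = var.to_dict()
        if first["name"]:
            row["gene"] = first["name"]
        row["strand"] = first["strand"]
        row["n_overlaps"] = len(hits)
        keep_rows.append(row)
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def filter_rare_variants(
    variants: pd.DataFrame,
    max_af: float = 0.01,
    require_snv: bool = True,
    somatic: bool = False,
    min_cosmic_cnt: int = 2,
) -> pd.DataFrame:
    """Frequency/recurrence filter for library inclusion.

    Population mode keeps SNVs with adjusted MAF strictly below ``max_af``
    (missing adjAF drops the variant; the number dropped is recorded in
    ``df.attrs['n_missing_af']``).  Somatic mode instead requires a sample
    count of at least ``min_cosmic_cnt`` (i.e. recurrence in >1 sample).
    """
    df = variants.copy()
    if require_snv:
        is_snv = df["ref"].isin(_VALID_BASES) & df["alt"].isin(_VALID_BASES)
        df = df[is_snv]
    df = df[df["ref"] != df["alt"]]
    if somatic:
        cnt = pd.to_numeric(df["cosmic_cnt"], errors="coerce")
        df = df[cnt >= min_cosmic_cnt]
        df.attrs["n_missing_af"] = 0
    else:
        af = pd.to_numeric(df["adjAF"], errors="coerce")
        n_missing = int(af.isna().sum())
        df = df[af.notna() & (af < max_af)]
        df.attrs["n_missing_af"] = n_missing
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sequence screening
# ---------------------------------------------------------------------------

def screen_sequences(
    inserts: Mapping[str, str] | Sequence[str],
    forbidden: Iterable[str] = DEFAULT_FORBIDDEN,
) -> tuple[list[str], pd.DataFrame]:
    """Partition inserts into cloning-compatible and rejected.

    An insert fails if it, or its reverse complement, contains any forbidden
    substring (restriction sites, subpool primers).  Returns the list of
    passing keys and a DataFrame of failures with the matched motif.
    """
    forbidden = list(forbidden)
    if not forbidden:
        raise ValueError("forbidden substring set must not be empty")
    if not isinstance(inserts, Mapping):
        inserts = {str(i): s for i, s in enumerate(inserts)}
    labels = {ECORI: "EcoRI", BAMHI: "BamHI"}
    passed, failures = [], []
    for key, seq in inserts.items():
        seq = seq.upper()
        rc = revcomp(seq)
        reason = None
        for motif in forbidden:
            if motif in seq or motif in rc:
                reason = labels.get(motif, motif)
                break
        if reason is None:
            passed.append(key)
        else:
            failures.append({"id": key, "reason": reason})
    return passed, pd.DataFrame(failures, columns=["id", "reason"])


# ---------------------------------------------------------------------------
# oligo assembly
# ---------------------------------------------------------------------------

@dataclass
class OligoRecord:
    oligo_id: str
    variant_id: str
    allele: str              # "ref" | "alt"
    subpool_id: str
    full_sequence: str
    insert_sequence: str
    variant_offset: int      # 0-based within insert

    def __post_init__(self) -> None:
        if self.insert_sequence[self.variant_offset] not in _VALID_BASES:
            raise ValueError("variant base is not A/C/G/T")


def _plus_strand_window(genome: Mapping[str, str], chrom: str, pos: int,
                        up: int, down: int) -> str:
    """Plus-strand genomic window [pos-up, pos+down] around a 1-based pos."""
    seq = genome[chrom]
    start = pos - 1 - up
    end = pos + down  # exclusive
    if start < 0 or end > len(seq):
        raise ValueError(
            f"variant {chrom}:{pos}: flanking context would extend beyond the "
            "available sequence; extend the annotated 3' UTR region"
        )
    return str(seq[start:end]).upper()


def assemble_oligo(
    variant: Mapping,
    genome: Mapping[str, str],
    layout: OligoLayout = DESIGN2,
    subpool_id: str = "sp1",
) -> tuple[OligoRecord, OligoRecord]:
    """Build the ref and alt oligos for one variant.

    The insert is the variant-centered window of ``layout.insert_len`` nt on
    the transcribed strand; for minus-strand variants the plus-strand window
    is reverse-complemented and the alleles complemented.  The two returned
    oligos differ at exactly ``layout.variant_offset`` within the insert.
    """
    offset = layout.variant_offset
    ins_len = layout.insert_len
    strand = variant.get("strand", "+") if hasattr(variant, "get") else variant["strand"]
    chrom, pos = variant["chrom"], int(variant["pos"])
    ref, alt = variant["ref"].upper(), variant["alt"].upper()
    if ref == alt or ref not in _VALID_BASES or alt not in _VALID_BASES:
        raise ValueError("ref/alt must be distinct single bases")

    if strand == "-":
        # after reverse complement the variant must land at `offset`
        up = ins_len - 1 - offset
        down = ins_len - 1 - up
        window = revcomp(_plus_strand_window(genome, chrom, pos, up, down))
        ref_b, alt_b = complement(ref), complement(alt)
    else:
        up = offset
        down = ins_len - 1 - offset
        window = _plus_strand_window(genome, chrom, pos, up, down)
        ref_b, alt_b = ref, alt

    if window[offset] != ref_b:
        raise ValueError(
            f"reference base mismatch at {chrom}:{pos}: genome has "
            f"{window[offset]!r} (transcribed strand), variant table says {ref_b!r}"
        )

    vid = variant.get("variant_id") if hasattr(variant, "get") else variant["variant_id"]
    vid = vid or f"{chrom}_{pos}_{ref}_{alt}"
    records = []
    for allele, base in (("ref", ref_b), ("alt", alt_b)):
        insert = window[:offset] + base + window[offset + 1:]
        records.append(
            OligoRecord(
                oligo_id=f"{vid}:{allele}",
                variant_id=vid,
                allele=allele,
                subpool_id=subpool_id,
                full_sequence=layout.assemble(insert),
                insert_sequence=insert,
                variant_offset=offset,
            )
        )
    return records[0], records[1]


def oligos_to_frame(oligos: Iterable[OligoRecord], layout: OligoLayout) -> pd.DataFrame:
    """Tabulate OligoRecords; adds the variant offset within the full oligo."""
    rows = []
    for o in oligos:
        rows.append(
            {
                "oligo_id": o.oligo_id,
                "variant_id": o.variant_id,
                "allele": o.allele,
                "subpool_id": o.subpool_id,
                "full_sequence": o.full_sequence,
                "insert_sequence": o.insert_sequence,
                "variant_offset": o.variant_offset,
                "full_variant_offset": layout.insert_start + o.variant_offset,
            }
        )
    return pd.DataFrame(rows)


def design_saturation_panel(
    spec: MotifSpec,
    context: str,
    motif_start: int,
    layout: OligoLayout = MOTIF_LAYOUT,
) -> pd.DataFrame:
    """Saturation-mutagenesis panel for a known motif.

    ``context`` is the tested insert sequence (length ``layout.insert_len``)
    with the motif beginning at 0-based ``motif_start``.  Every position in
    the motif and its flanks (``spec.flank_up`` upstream, ``spec.flank_down``
    downstream) is mutated to the 3 alternative bases, giving
    ``1 + 3 * (motif_len + flank_up + flank_down)`` oligos including the
    reference.
    """
    context = context.upper()
    if len(context) != layout.insert_len:
        raise ValueError("context length must equal layout insert_len")
    if set(context) - _VALID_BASES:
        raise ValueError("ambiguous base in context sequence")
    m = len(spec.motif_sequence)
    lo = motif_start - spec.flank_up
    hi = motif_start + m + spec.flank_down  # exclusive
    if lo < 0 or hi > len(context):
        raise ValueError("context does not cover motif plus flanks")
    if context[motif_start:motif_start + m].upper() != spec.motif_sequence.upper().replace("U", "T"):
        raise ValueError("motif sequence not found at motif_start in context")

    rows = [
        {
            "oligo_id": f"{spec.motif_id}:ref",
            "motif_id": spec.motif_id,
            "position": -1,
            "allele": context[motif_start],
            "region": "reference",
            "insert_sequence": context,
            "full_sequence": layout.assemble(context),
        }
    ]
    for i in range(lo, hi):
        ref_base = context[i]
        region = "motif" if motif_start <= i < motif_start + m else "flank"
        for b in "ACGT":
            if b == ref_base:
                continue
            mutated = context[:i] + b + context[i + 1:]
            rows.append(
                {
                    "oligo_id": f"{spec.motif_id}:{i}{ref_base}>{b}",
                    "motif_id": spec.motif_id,
                    "position": i,
                    "allele": b,
                    "region": region,
                    "insert_sequence": mutated,
                    "full_sequence": layout.assemble(mutated),
                }
            )
    return pd.DataFrame(rows)
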