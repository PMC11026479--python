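"""Structured read parsing, library matching, and UMI deduplication.

Read 1 of each pair carries, in fixed-width segments: a 15-nt UMI, the 14-nt
reverse-transcription primer, a 6-nt restriction site (REC2), the 15-nt
subpool primer, and the first 100 nt of the designed oligo.  Read 2 is the
designed sequence (reverse-complement orientation by sequencing convention;
the matcher auto-detects orientation).

Because the reference set is small, fixed-length and fully enumerable, reads
are assigned with a hash of exact design fragments plus 1-substitution
neighborhood probing rather than a general-purpose aligner.  A read is
assigned to a reference iff it has at most one mismatch against it across
read 1's design fragment and read 2 combined, and no mismatch falls on the
designed SNP position of that reference; ties between equally good
references leave the read unmapped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq import revcomp

DEFAULT_RT_PRIMER = "TCTTTCCCTACACG"   # 14 nt
DEFAULT_REC2 = "GGATCC"                # 6 nt


@dataclass(frozen=True)
class ReadLayout:
    """Fixed-width segment lengths of read 1."""

    umi_len: int = 15
    rt_primer_len: int = 14
    rec2_len: int = 6
    subpool_len: int = 15
    design_frag_len: int = 100

    @property
    def total(self) -> int:
        return (self.umi_len + self.rt_primer_len + self.rec2_len
                + self.subpool_len + self.design_frag_len)


def parse_read1(read1: str, layout: ReadLayout = ReadLayout()):
    """Slice read 1 into (umi, fixed segments, design fragment).

    Returns ``None`` for reads shorter than the layout sum (the caller counts
    these as QC drops).  No sequence validation is performed here.
    """
    if len(read1) < layout.total:
        return None
    pos = 0
    umi = read1[pos:pos + layout.umi_len]; pos += layout.umi_len
    rt = read1[pos:pos + layout.rt_primer_len]; pos += layout.rt_primer_len
    rec2 = read1[pos:pos + layout.rec2_len]; pos += layout.rec2_len
    subpool = read1[pos:pos + layout.subpool_len]; pos += layout.subpool_len
    frag = read1[pos:pos + layout.design_frag_len]
    return umi, (rt, rec2, subpool), frag


class LibraryIndex:
    """Exact-fragment hash plus 1-substitution probing over designed oligos.

    Built from the design table (``oligo_id``, ``full_sequence``,
    ``full_variant_offset``); both alleles of a variant are distinct
    references.
    """

    def __init__(self, design: pd.DataFrame, layout: ReadLayout = ReadLayout()):
        self.layout = layout
        self.oligo_ids = list(design["oligo_id"])
        self.full = dict(zip(design["oligo_id"], design["full_sequence"]))
        if "full_variant_offset" in design:
            self.snp_offset = dict(
                zip(design["oligo_id"], design["full_variant_offset"])
            )
        else:
            self.snp_offset = {oid: -1 for oid in self.oligo_ids}
        self._frag_index: dict[str, list[str]] = defaultdict(list)
        for oid, seq in self.full.items():
            self._frag_index[seq[: layout.design_frag_len]].append(oid)

    def _candidates(self, frag: str) -> set[str]:
        cand = set(self._frag_index.get(frag, ()))
        if not cand:
            for i, orig in enumerate(frag):
                for b in "ACGT":
                    if b == orig:
                        continue
                    probe = frag[:i] + b + frag[i + 1:]
                    cand.update(self._frag_index.get(probe, ()))
        return cand

    def _mismatches(self, oid: str, frag: str, read2: str | None):
        """(total mismatches, mismatch positions on the full oligo), or None
        if comparison is impossible.  Read-2 orientation is auto-detected."""
        full = self.full[oid]
        positions = []
        for i, (a, b) in enumerate(zip(frag, full)):
            if a != b:
                positions.append(i)
                if len(positions) > 2:
                    return None
        if read2 is not None and read2:
            n = min(len(read2), len(full))
            # read 2 covers the 3' end of the oligo; try reverse complement
            # first (standard paired-end orientation), then as-is.
            best = None
            for oriented in (revcomp(read2)[::], read2):
                tail_ref = full[len(full) - n:]
                tail_read = oriented[-n:] if len(oriented) >= n else oriented
                if len(tail_read) != n:
                    continue
                mm = [len(full) - n + j
                      for j in range(n) if tail_read[j] != tail_ref[j]]
                if best is None or len(mm) < len(best):
                    best = mm
            if best is None:
                return None
            # positions double-covered by both reads are merged
            merged = set(positions) | set(best)
            return len(merged), merged
        return len(positions), set(positions)

    def match(self, frag: str, read2: str | None = None,
              max_mismatches: int = 1) -> str | None:
        """Assign a read pair to an oligo id, or ``None`` (unmapped)."""
        cand = self._candidates(frag)
        best_oid, best_mm, tie = None, None, False
        for oid in cand:
            res = self._mismatches(oid, frag, read2)
            if res is None:
                continue
            mm, positions = res
            if mm > max_mismatches:
                continue
            if self.snp_offset[oid] in positions:
                continue  # mismatch at the designed SNP: never accepted
            if best_mm is None or mm < best_mm:
                best_oid, best_mm, tie = oid, mm, False
            elif mm == best_mm:
                tie = True
        if best_oid is None or tie:
            return None
        return best_oid


def dedup_umis(assignments) -> pd.DataFrame:
    """Collapse PCR duplicates: one count per distinct (UMI, oligo) pair.

    ``assignments`` is an iterable of ``(umi, oligo_id)``.  Returns a table
    of raw read counts and deduplicated family counts per oligo.
    """
    raw = defaultdict(int)
    fams = defaultdict(set)
    for umi, oid in assignments:
        raw[oid] += 1
        fams[oid].add(umi)
    rows = [
        {"oligo_id": oid, "raw": raw[oid], "dedup": len(fams[oid])}
        for oid in sorted(raw)
    ]
    return pd.DataFrame(rows, columns=["oligo_id", "raw", "dedup"])


def mismatch_profile(alignments, index: LibraryIndex,
                     primer_exclude: int = 15) -> pd.DataFrame:
    """Per-position mismatch rate over the designed sequences.

    ``alignments`` is an iterable of ``(oligo_id, frag, read2)``.  For each
    design position the rate is 100 * mismatching / covering reads; positions
    within ``primer_exclude`` nt of either end of the oligo are excluded, and
    positions with zero coverage are reported with a missing rate (NaN).
    """
    length = max(len(s) for s in index.full.values())
    covering = np.zeros(length, dtype=int)
    mismatching = np.zeros(length, dtype=int)
    for oid, frag, read2 in alignments:
        full = index.full[oid]
        for i, (a, b) in enumerate(zip(frag, full)):
            covering[i] += 1
            if a != b:
                mismatching[i] += 1
        if read2:
            n = min(len(read2), len(full))
            oriented = revcomp(read2)
            tail_ref = full[len(full) - n:]
            tail_read = oriented[-n:]
            start = len(full) - n
            for j in range(n):
                covering[start + j] += 1
                if tail_read[j] != tail_ref[j]:
                    mismatching[start + j] += 1
    rate = np.full(length, np.nan)
    nz = covering > 0
    rate[nz] = 100.0 * mismatching[nz] / covering[nz]
    df = pd.DataFrame(
        {"position": np.arange(length), "covering": covering,
         "mismatching": mismatching, "rate_percent": rate}
    )
    return df[(df.position >= primer_exclude) & (df.position < length - primer_exclude)
              ].reset_index(drop=True)


def allele_frequency(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-variant allele frequency alt/(alt+ref) from deduplicated counts.

    ``counts`` must carry oligo_id, replicate, library_type and dedup columns;
    the design table maps oligos to (variant_id, allele).  AF is NaN when both
    allele counts are zero.
    """
    merged = counts.merge(
        design[["oligo_id", "variant_id", "allele"]], on="oligo_id", how="left"
    )
    wide = (
        merged.pivot_table(
            index=["variant_id", "replicate", "library_type"],
            columns="allele", values="dedup", aggfunc="sum", fill_value=0,
        )
        .reindex(columns=["ref", "alt"], fill_value=0)
        .reset_index()
    )
    total = wide["ref"] + wide["alt"]
    wide["af"] = np.where(total > 0, wide["alt"] / total.replace(0, np.nan), np.nan)
    return wide


@dataclass
class ProcessResult:
    counts: pd.DataFrame     # oligo_id, replicate, library_type, raw, dedup
    qc: dict                 # parse drops, unmapped counts
    alignments: list         # (oligo_id, frag, read2) of mapped reads


def process_reads(
    read_pairs: dict,
    index: LibraryIndex,
    layout: ReadLayout = ReadLayout(),
) -> ProcessResult:
    """Full counting pipeline over ``{(library_type, replicate): [(name, r1, r2)]}``.

    Produces the deduplicated CountMatrix in tidy form together with QC
    tallies (short-read drops, unmapped reads).
    """
    all_counts = []
    qc = {"parsed": 0, "dropped_short": 0, "unmapped": 0, "mapped": 0}
    alignments = []
    for (lib, rep), pairs in sorted(read_pairs.items()):
        assignments = []
        for _name, r1, r2 in pairs:
            parsed = parse_read1(r1, layout)
            if parsed is None:
                qc["dropped_short"] += 1
                continue
            qc["parsed"] += 1
            umi, _fixed, frag = parsed
            oid = index.match(frag, r2)
            if oid is None:
                qc["unmapped"] += 1
                continue
            qc["mapped"] += 1
            assignments.append((umi, oid))
            alignments.append((oid, frag, r2))
        counts = dedup_umis(assignments)
        counts["replicate"] = rep
        counts["library_type"] = lib
        all_counts.append(counts)
    counts = (
        pd.concat(all_counts, ignore_index=True)
        if all_counts
        else pd.DataFrame(columns=["oligo_id", "raw", "dedup", "replicate", "library_type"])
    )
    return ProcessResult(counts=counts, qc=qc, alignments=alignments)
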