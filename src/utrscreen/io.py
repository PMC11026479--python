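"""File I/O: FASTA/FASTQ via Biopython, TSV tables, YAML run manifests."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(reads, path, quality_char: str = "I") -> None:
    """Write (name, sequence) pairs as 4-line FASTQ with constant quality."""
    with _open(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path):
    """Yield (name, sequence) from a (optionally gzipped) FASTQ file."""
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def write_read_pairs(reads: dict, outdir) -> dict:
    """Write simulated read pairs per (library_type, replicate) to FASTQ.

    Returns a map of (library_type, replicate) -> (r1 path, r2 path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for (lib, rep), pairs in sorted(reads.items()):
        p1 = outdir / f"{lib}_rep{rep}_R1.fastq"
        p2 = outdir / f"{lib}_rep{rep}_R2.fastq"
        write_fastq(((n, r1) for n, r1, _ in pairs), p1)
        write_fastq(((n, r2) for n, _, r2 in pairs), p2)
        paths[(lib, rep)] = (str(p1), str(p2))
    return paths


def write_tsv(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_manifest(config, path) -> None:
    """Echo all simulation parameters (incl. seed) to a YAML manifest."""
    payload = config.manifest() if hasattr(config, "manifest") else dict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
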