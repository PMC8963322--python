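"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Bio.SeqIO; tabular outputs are TSV via pandas;
coverage is exported as bedgraph (one track per strand).
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALIGNMENT_COLUMNS = ["read_id", "contig_id", "start", "end", "strand",
                     "matches", "match_fraction"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read small-RNA reads from FASTQ or FASTA (by extension)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fq", ".fastq")) else "fasta"
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]
    if not reads:
        raise ValueError(f"no reads found in {path}")
    return reads


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike,
                quality: int = 40) -> None:
    """Write reads as FASTQ with a constant quality (inserts are pre-trimmed)."""
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def alignments_to_frame(alignments) -> pd.DataFrame:
    rows = [(a.read_id, a.contig_id, a.start, a.end, a.strand,
             a.matches, a.match_fraction) for a in alignments]
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def write_alignments(alignments, path: str | os.PathLike) -> None:
    alignments_to_frame(alignments).to_csv(path, sep="\t", index=False)


def read_alignments(path: str | os.PathLike):
    from .mapper import ReadAlignment

    df = pd.read_csv(path, sep="\t")
    return [ReadAlignment(row.read_id, row.contig_id, int(row.start), int(row.end),
                          row.strand, int(row.matches), float(row.match_fraction))
            for row in df.itertuples()]


def write_bedgraph(coverage, path: str | os.PathLike) -> None:
    """Export StrandedCoverage objects as a two-track bedgraph file."""
    with open(path, "w") as fh:
        for strand in ("sense", "antisense"):
            fh.write(f'track type=bedGraph name="{strand}"\n')
            for cov in coverage.values():
                depth = cov.sense if strand == "sense" else cov.antisense
                start = 0
                for i in range(1, len(depth) + 1):
                    if i == len(depth) or depth[i] != depth[start]:
                        if depth[start] > 0:
                            fh.write(f"{cov.contig_id}\t{start}\t{i}\t{int(depth[start])}\n")
                        start = i


def read_screening_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a (population, n_screened, n_positive) TSV screening table."""
    df = pd.read_csv(path, sep="\t")
    expected = {"population", "n_screened", "n_positive"}
    if not expected <= set(df.columns):
        raise ValueError(f"screening table must have columns {sorted(expected)}")
    return df
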