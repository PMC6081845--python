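"""FASTA/FASTQ/TSV round-tripping for the pipeline's file surfaces."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quant import ExpressionTable
from .reference import TranscriptRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_expression_tsv",
    "write_expression_tsv",
]


def _infer_source(transcript_id: str) -> str:
    if transcript_id.startswith("NM_"):
        return "refseq_nm"
    if transcript_id.startswith("XM_"):
        return "refseq_xm"
    return "ensembl"


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcript records; gene and source are kept in the header."""
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.transcript_id,
            description=f"gene:{r.gene_id or '-'} source:{r.source} biotype:{r.biotype}",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            part.split(":", 1) for part in rec.description.split()[1:] if ":" in part
        )
        gene = fields.get("gene")
        out.append(
            TranscriptRecord(
                transcript_id=rec.id,
                sequence=str(rec.seq).upper(),
                source=fields.get("source", _infer_source(rec.id)),
                gene_id=None if gene in (None, "-") else gene,
                biotype=fields.get("biotype", "protein_coding"),
            )
        )
    return out


def write_fastq(reads: Sequence[str], sample_id: str, path: str | Path) -> None:
    """Write sequence-mode reads as FASTQ with uniform placeholder quality."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{sample_id}.{i}\n{read}\n+\n{'I' * len(read)}\n")


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6f")


def read_expression_tsv(path: str | Path, level: str = "gene") -> ExpressionTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(values, level)
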