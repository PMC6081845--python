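"""Reference-transcriptome construction and iterative revision.

A meta-atlas quantifies every library against one fixed "RNA space": the
union of curated CDS models (Ensembl-style) and mRNA records (RefSeq-style
NM/XM), made non-redundant.  mRNA records carry UTRs, so they can wholly
contain a CDS that is already in the curated set; such records add no new
coding information and are dropped.  After a first quantification pass the
reference is revised once, removing transcripts that are effectively
undetectable across tissues, and expression is re-quantified against the
revised set.

Merge rules
-----------
1. Every curated (Ensembl-source) CDS is a candidate.
2. RefSeq mRNAs are trimmed to their longest ORF (UTRs removed).
3. A RefSeq whose trimmed sequence is already present under any other
   identifier is dropped (one copy retained, under the curated identifier).
4. A predicted (XM) record whose gene already has curated models and whose
   untrimmed sequence contains any of that gene's curated CDS as a substring
   is dropped: the curated model is considered better supported.
5. Any CDS shorter than 300 nt is dropped, to limit spurious k-mer mapping
   from short sequences.

Every exclusion is logged with a single reason code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "TranscriptRecord",
    "ExclusionRecord",
    "ReferenceSet",
    "trim_utrs",
    "dedupe_union",
    "revise_transcriptome",
    "MIN_CDS_LENGTH",
]

MIN_CDS_LENGTH = 300

_STOPS = {"TAA", "TAG", "TGA"}
_VALID_SEQ = re.compile(r"^[ACGTN]+$")

Source = Literal["ensembl", "refseq_nm", "refseq_xm"]


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript sequence with its provenance.

    ``gene_id`` may be ``None`` for predicted records that could not be
    assigned to a known gene; downstream these are treated as singleton
    genes named after the transcript.
    """

    transcript_id: str
    sequence: str
    source: Source
    gene_id: str | None = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        if self.source not in ("ensembl", "refseq_nm", "refseq_xm"):
            raise ValueError(f"{self.transcript_id}: unknown source {self.source!r}")

    @property
    def effective_gene_id(self) -> str:
        """Gene id, or the transcript id itself for orphan records."""
        return self.gene_id if self.gene_id is not None else self.transcript_id


@dataclass(frozen=True)
class ExclusionRecord:
    transcript_id: str
    reason: str
    iteration: int
    detail: str = ""


@dataclass
class ReferenceSet:
    """A non-redundant reference transcriptome plus its exclusion log."""

    records: list[TranscriptRecord]
    iteration: int = 1
    exclusions: list[ExclusionRecord] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [r.transcript_id for r in self.records]

    def tx2gene(self) -> dict[str, str]:
        return {r.transcript_id: r.effective_gene_id for r in self.records}

    def exclusion_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.transcript_id, e.reason, e.iteration, e.detail) for e in self.exclusions],
            columns=["transcript_id", "reason", "iteration", "detail"],
        )


def trim_utrs(mrna: str) -> str:
    """Trim an mRNA to its longest ORF, removing 5' and 3' UTRs.

    Scans all three forward frames for ATG...stop open reading frames
    (mRNAs are sense-strand, so the reverse strand is never searched) and
    returns the longest, stop codon included.  Ties between equal-length
    ORFs are broken in favour of the 5'-most start.  Returns ``""`` when no
    complete ORF exists; callers log such records for exclusion.
    """
    seq = mrna.upper()
    if not seq:
        raise ValueError("empty mRNA sequence")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")

    best_start, best_len = -1, 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                orf_len = i + 3 - start
                # strictly greater: ties resolve to the earlier (5'-most) start
                if orf_len > best_len or (orf_len == best_len and start < best_start):
                    best_start, best_len = start, orf_len
                start = None
    if best_len == 0:
        return ""
    return seq[best_start : best_start + best_len]


def dedupe_union(
    ensembl: Sequence[TranscriptRecord],
    refseq: Sequence[TranscriptRecord],
) -> ReferenceSet:
    """Merge a curated CDS set with a RefSeq mRNA set into one reference.

    Applies, in order: ORF trimming of RefSeq records, exact-sequence
    deduplication against everything already retained, the XM
    CDS-incorporation rule, and the >= 300 nt CDS length floor.  All drops
    are logged with one reason each.
    """
    exclusions: list[ExclusionRecord] = []
    kept: list[TranscriptRecord] = []
    seen: dict[str, str] = {}  # sequence -> id already holding it

    # Curated CDS by gene, untrimmed, for the XM incorporation test.
    ens_cds_by_gene: dict[str, list[str]] = {}
    for rec in ensembl:
        ens_cds_by_gene.setdefault(rec.effective_gene_id, []).append(rec.sequence)
    ens_gene_ids = {r.effective_gene_id for r in ensembl}

    for rec in sorted(ensembl, key=lambda r: r.transcript_id):
        if rec.sequence in seen:
            exclusions.append(
                ExclusionRecord(rec.transcript_id, "duplicate_sequence", 1, seen[rec.sequence])
            )
            continue
        if len(rec.sequence) < MIN_CDS_LENGTH:
            exclusions.append(ExclusionRecord(rec.transcript_id, "short_cds", 1, str(len(rec.sequence))))
            continue
        seen[rec.sequence] = rec.transcript_id
        kept.append(rec)

    for rec in sorted(refseq, key=lambda r: r.transcript_id):
        # XM rule is evaluated on the untrimmed mRNA: UTR-bearing records can
        # encapsulate a curated CDS even though the trimmed ORFs differ.
        if rec.source == "refseq_xm" and rec.gene_id is not None and rec.gene_id in ens_gene_ids:
            contained = next(
                (cds for cds in ens_cds_by_gene.get(rec.gene_id, []) if cds in rec.sequence), None
            )
            if contained is not None:
                exclusions.append(
                    ExclusionRecord(rec.transcript_id, "incorporates_ensembl_cds", 1)
                )
                continue
        orf = trim_utrs(rec.sequence)
        if not orf:
            exclusions.append(ExclusionRecord(rec.transcript_id, "no_orf", 1))
            continue
        if orf in seen:
            exclusions.append(
                ExclusionRecord(rec.transcript_id, "duplicate_sequence", 1, seen[orf])
            )
            continue
        if len(orf) < MIN_CDS_LENGTH:
            exclusions.append(ExclusionRecord(rec.transcript_id, "short_cds", 1, str(len(orf))))
            continue
        seen[orf] = rec.transcript_id
        kept.append(
            TranscriptRecord(
                transcript_id=rec.transcript_id,
                sequence=orf,
                source=rec.source,
                gene_id=rec.gene_id,
                biotype=rec.biotype,
            )
        )

    return ReferenceSet(records=kept, iteration=1, exclusions=exclusions)


def revise_transcriptome(
    ref: ReferenceSet,
    first_pass,
    failed_samples: Iterable[str],
    *,
    detect_tpm: float = 1.0,
    single_tissue_filter: bool = True,
) -> ReferenceSet:
    """Build the iteration-2 reference from first-pass expression.

    A transcript is *detectable* in a tissue when its tissue average —
    median TPM over replicate samples, per study (BioProject), per tissue,
    Zipf-failed samples excluded — exceeds ``detect_tpm``.  Drops, with one
    logged reason each:

    - ``low_expression``: not detectable in any tissue;
    - ``only_in_failed_samples``: as above, but the transcript did exceed
      the detection level in at least one excluded (Zipf-failed) sample;
    - ``single_tissue`` (optional, default on): detectable in exactly one
      tissue, a likely artefact of uneven sequencing depth.
    """
    from .atlas import aggregate  # local import to avoid a cycle

    failed = set(failed_samples)
    unknown = failed - set(first_pass.sample_ids)
    if unknown:
        raise KeyError(f"failed_samples not in expression table: {sorted(unknown)}")

    good = first_pass.subset_samples([s for s in first_pass.sample_ids if s not in failed])
    agg = aggregate(good)
    # tissue-level average: collapse (bioproject, tissue) columns per tissue by median
    tissue_avg = agg.values.T.groupby(agg.meta["tissue"]).median().T

    kept: list[TranscriptRecord] = []
    exclusions = list(ref.exclusions)
    failed_vals = first_pass.values[list(failed)] if failed else None

    for rec in ref.records:
        tid = rec.transcript_id
        if tid not in tissue_avg.index:
            n_detect = 0
        else:
            n_detect = int((tissue_avg.loc[tid] > detect_tpm).sum())
        if n_detect == 0:
            in_failed = bool(
                failed_vals is not None
                and tid in failed_vals.index
                and (failed_vals.loc[tid] > detect_tpm).any()
            )
            reason = "only_in_failed_samples" if in_failed else "low_expression"
            exclusions.append(ExclusionRecord(tid, reason, 2))
            continue
        if single_tissue_filter and n_detect == 1:
            exclusions.append(ExclusionRecord(tid, "single_tissue", 2))
            continue
        kept.append(rec)

    return ReferenceSet(records=kept, iteration=2, exclusions=exclusions)
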