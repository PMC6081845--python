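"""Synthetic inputs with the statistical structure the atlas assumes.

Everything downstream — reference merging, down-sampling, quantification,
Zipf QC, tissue specificity, clustering, annotation — is exercised on data
from this module, so each generator reproduces the relevant structure of
the real inputs:

- transcript abundances follow Zipf's law (abundance of the gene of rank r
  proportional to 1/r) with multiplicative lognormal noise, so a minority
  of genes account for the majority of reads;
- tissue identity is a multiplicative fold-change on disjoint planted gene
  clusters, renormalised to proportions, giving detectable co-expression;
- the two transcript sources overlap: some mRNA (RefSeq-style) records are
  a curated CDS plus flanking UTRs, some are predictions incorporating a
  curated CDS, some encode genuinely novel ORFs, and some CDS fall under
  the 300 nt floor;
- annotation fixtures span every quality category 1-8 plus 'unannotated',
  and orthology/PPI fixtures place rows on both sides of every filter.

All generators are deterministic for a fixed seed; per-sample streams are
split by sample id, so adding samples never perturbs existing ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .reference import TranscriptRecord

__all__ = [
    "TranscriptomeConfig",
    "ReadLibrary",
    "SampleSpec",
    "PlantedCluster",
    "AtlasTruth",
    "AnnotationFixtures",
    "make_transcriptome",
    "make_truth",
    "simulate_library",
    "make_annotation_fixtures",
]

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [c for c in _CODONS if c not in _STOP_CODONS and c != "ATG"]

DEFAULT_MEAN_FRAGMENT = 100
SEQUENCE_MODE_DEPTH_CAP = 200_000


# ---------------------------------------------------------------------------
# transcriptome generation


@dataclass(frozen=True)
class TranscriptomeConfig:
    """Fractions of genes falling into each source-overlap scenario.

    The remaining genes get a plain curated (Ensembl-style) CDS only.
    Fraction sums above 1 are rejected.
    """

    frac_refseq_only: float = 0.10      # gene absent from the curated set; NM only
    frac_xm_incorporating: float = 0.10  # predicted mRNA containing the curated CDS
    frac_xm_novel: float = 0.10          # predicted mRNA with a genuinely novel CDS
    frac_nm_duplicate: float = 0.10      # validated mRNA = curated CDS + UTRs
    frac_short_cds: float = 0.05         # curated CDS under the 300 nt floor
    cds_codons: tuple[int, int] = (110, 800)   # CDS length range, in codons
    short_cds_codons: tuple[int, int] = (40, 98)
    utr_length: tuple[int, int] = (17, 150)

    def counts(self, n_genes: int) -> dict[str, int]:
        fracs = {
            "refseq_only": self.frac_refseq_only,
            "xm_incorporating": self.frac_xm_incorporating,
            "xm_novel": self.frac_xm_novel,
            "nm_duplicate": self.frac_nm_duplicate,
            "short_cds": self.frac_short_cds,
        }
        if any(f < 0 for f in fracs.values()) or sum(fracs.values()) > 1 + 1e-12:
            raise ValueError("scenario fractions must be non-negative and sum to <= 1")
        counts = {k: int(round(f * n_genes)) for k, f in fracs.items()}
        while sum(counts.values()) > n_genes:  # rounding overflow
            counts[max(counts, key=counts.get)] -= 1
        return counts


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A complete ORF: ATG, non-stop/non-ATG codons, one stop.

    Internal ATG codons are avoided so the longest ORF of any sequence
    embedding this CDS between pyrimidine-only UTRs is the CDS itself.
    """
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + str(rng.choice(_STOP_CODONS))


def _random_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    # pyrimidine-only: cannot contain ATG or a stop codon in any frame
    return "".join(rng.choice(["C", "T"], size=int(rng.integers(lo, hi + 1))))


def make_transcriptome(
    n_genes: int,
    seed: int,
    cfg: TranscriptomeConfig | None = None,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Generate two overlapping transcript sets (curated CDS + mRNAs).

    Returns ``(ensembl_set, refseq_set)``.  All sequences start with ATG
    and end with a stop codon closing the longest ORF.  Scenario counts
    are exact: ``round(frac * n_genes)`` genes per scenario, assigned to
    deterministic gene blocks.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    cfg = cfg or TranscriptomeConfig()
    counts = cfg.counts(n_genes)
    rng = stream(seed, "transcriptome")

    scenarios = list(
        itertools.chain.from_iterable([name] * n for name, n in counts.items())
    )
    scenarios += ["plain"] * (n_genes - len(scenarios))

    ensembl: list[TranscriptRecord] = []
    refseq: list[TranscriptRecord] = []
    lo, hi = cfg.cds_codons
    for i, scenario in enumerate(scenarios):
        gene = f"GSYN{i:05d}"
        ens_id = f"ENSSYNT{i:07d}"
        cds = _random_cds(rng, int(rng.integers(lo, hi + 1)))
        utr5 = _random_utr(rng, *cfg.utr_length)
        utr3 = _random_utr(rng, *cfg.utr_length)
        if scenario == "refseq_only":
            refseq.append(TranscriptRecord(f"NM_9{i:06d}", utr5 + cds + utr3, "refseq_nm", gene))
        elif scenario == "xm_incorporating":
            ensembl.append(TranscriptRecord(ens_id, cds, "ensembl", gene))
            refseq.append(TranscriptRecord(f"XM_9{i:06d}", utr5 + cds + utr3, "refseq_xm", gene))
        elif scenario == "xm_novel":
            ensembl.append(TranscriptRecord(ens_id, cds, "ensembl", gene))
            novel = _random_cds(rng, int(rng.integers(lo, hi + 1)))
            refseq.append(TranscriptRecord(f"XM_9{i:06d}", utr5 + novel + utr3, "refseq_xm", gene))
        elif scenario == "nm_duplicate":
            ensembl.append(TranscriptRecord(ens_id, cds, "ensembl", gene))
            refseq.append(TranscriptRecord(f"NM_9{i:06d}", utr5 + cds + utr3, "refseq_nm", gene))
        elif scenario == "short_cds":
            short = _random_cds(rng, int(rng.integers(*cfg.short_cds_codons)))
            ensembl.append(TranscriptRecord(ens_id, short, "ensembl", gene))
        else:
            ensembl.append(TranscriptRecord(ens_id, cds, "ensembl", gene))
    return ensembl, refseq


# ---------------------------------------------------------------------------
# abundance truth and library simulation


@dataclass(frozen=True)
class PlantedCluster:
    cluster_id: str
    genes: tuple[str, ...]
    tissues: tuple[str, ...]
    fold_up: float

    def __post_init__(self) -> None:
        if self.fold_up <= 1:
            raise ValueError("fold_up must exceed 1")


@dataclass(frozen=True)
class SampleSpec:
    """Descriptor of one library to simulate."""

    sample_id: str
    tissue: str
    bioproject: str
    stage: str = "adult"
    zipf_alpha: float | None = None   # override: abundance ~ rank^(-alpha)
    replicate_sigma: float = 0.25     # lognormal replicate noise (log-e sd)


@dataclass
class AtlasTruth:
    """Ground truth for a simulated meta-dataset.

    ``baseline`` holds per-gene positive abundances (Zipf-ranked with
    multiplicative lognormal noise); ``tissue_proportions`` the expected
    per-tissue transcript proportions after applying planted fold-changes
    and renormalising (each column sums to 1).  Every planted gene belongs
    to exactly one cluster.
    """

    gene_ids: list[str]
    tissue_ids: list[str]
    baseline: pd.Series
    planted_clusters: dict[str, PlantedCluster]
    tissue_proportions: pd.DataFrame
    lengths: pd.Series
    seed: int
    zipf_alpha: float = 1.0
    zipf_sigma: float = 0.25

    def __post_init__(self) -> None:
        sums = self.tissue_proportions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("tissue proportions must sum to 1")
        seen: set[str] = set()
        for pc in self.planted_clusters.values():
            overlap = seen & set(pc.genes)
            if overlap:
                raise ValueError(f"genes in more than one planted cluster: {sorted(overlap)[:5]}")
            seen |= set(pc.genes)

    def planted_tissue(self, cluster_id: str) -> str:
        return self.planted_clusters[cluster_id].tissues[0]

    def sample_proportions(self, sample: SampleSpec) -> pd.Series:
        """Expected transcript proportions for one library.

        The tissue profile (or a rank-power profile when ``zipf_alpha`` is
        overridden, used to plant QC failures) is perturbed by lognormal
        replicate noise drawn from the sample's own stream, then
        renormalised.
        """
        if sample.tissue not in self.tissue_ids:
            raise KeyError(f"unknown tissue {sample.tissue!r}")
        if sample.zipf_alpha is not None:
            ranks = np.arange(1, len(self.gene_ids) + 1, dtype=float)
            order = np.argsort(-self.baseline.to_numpy())
            w = np.empty(len(ranks))
            w[order] = ranks ** (-sample.zipf_alpha)
            base = pd.Series(w, index=self.gene_ids)
        else:
            base = self.tissue_proportions[sample.tissue]
        rng = stream(self.seed, "replicate", sample.sample_id)
        noisy = base * rng.lognormal(0.0, sample.replicate_sigma, size=len(base))
        return noisy / noisy.sum()


def make_truth(
    n_genes: int,
    seed: int,
    n_tissues: int = 6,
    n_clusters: int = 6,
    cluster_size: int = 25,
    fold_up: float = 8.0,
    zipf_alpha: float = 1.0,
    zipf_sigma: float = 0.25,
    gene_ids: Sequence[str] | None = None,
    lengths: Mapping[str, int] | None = None,
) -> AtlasTruth:
    """Plant a Zipf-ranked abundance baseline and tissue-specific clusters.

    Baseline abundance of the gene of rank r is r^(-zipf_alpha) times
    lognormal noise of log-sd ``zipf_sigma``.  Each planted cluster is a
    random disjoint gene subset up-regulated ``fold_up``-fold in one
    tissue (tissue c = cluster c mod n_tissues).
    """
    if n_clusters * cluster_size > n_genes:
        raise ValueError("planted clusters exceed the gene count")
    rng = stream(seed, "truth")
    genes = list(gene_ids) if gene_ids is not None else [f"GSYN{i:05d}" for i in range(n_genes)]
    if len(genes) != n_genes:
        raise ValueError("gene_ids length mismatch")
    tissues = [f"tissue{t:02d}" for t in range(n_tissues)]
    ranks = np.arange(1, n_genes + 1, dtype=float)
    baseline = pd.Series(
        ranks ** (-zipf_alpha) * rng.lognormal(0.0, zipf_sigma, size=n_genes), index=genes
    )

    chosen = rng.choice(n_genes, size=n_clusters * cluster_size, replace=False)
    clusters: dict[str, PlantedCluster] = {}
    for c in range(n_clusters):
        members = tuple(genes[i] for i in sorted(chosen[c * cluster_size : (c + 1) * cluster_size]))
        tissue = tissues[c % n_tissues]
        clusters[f"planted{c:02d}"] = PlantedCluster(f"planted{c:02d}", members, (tissue,), fold_up)

    props = {}
    for tissue in tissues:
        w = baseline.copy()
        for pc in clusters.values():
            if tissue in pc.tissues:
                w.loc[list(pc.genes)] *= pc.fold_up
        props[tissue] = w / w.sum()
    lens = (
        pd.Series({g: int(lengths[g]) for g in genes})
        if lengths is not None
        else pd.Series(1000, index=genes)
    )
    return AtlasTruth(
        gene_ids=genes,
        tissue_ids=tissues,
        baseline=baseline,
        planted_clusters=clusters,
        tissue_proportions=pd.DataFrame(props),
        lengths=lens,
        seed=seed,
        zipf_alpha=zipf_alpha,
        zipf_sigma=zipf_sigma,
    )


@dataclass
class ReadLibrary:
    """A sequencing library: explicit reads, or abstract per-transcript counts."""

    sample_id: str
    layout: Literal["single", "paired"] = "single"
    reads: list[str] | None = None
    mates: list[str] | None = None
    counts: pd.Series | None = None
    read_length: int = 75

    def __post_init__(self) -> None:
        if (self.reads is None) == (self.counts is None):
            raise ValueError("exactly one of reads/counts must be given")
        if self.reads is not None and any(len(r) == 0 for r in self.reads):
            raise ValueError("empty read")
        if self.layout == "paired":
            if self.reads is not None and (self.mates is None or len(self.mates) != len(self.reads)):
                raise ValueError("paired layout requires equal mate counts")

    @property
    def mode(self) -> str:
        return "abstract" if self.counts is not None else "sequence"

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum()) if self.counts is not None else len(self.reads)


def _sampling_probs(truth: AtlasTruth, sample: SampleSpec, mean_fragment: int) -> pd.Series:
    from .quant import effective_length

    p = truth.sample_proportions(sample)
    eff = truth.lengths.map(lambda l: effective_length(int(l), mean_fragment))
    q = p * eff
    return q / q.sum()


def simulate_library(
    truth: AtlasTruth,
    sample: SampleSpec,
    depth: int,
    seed: int,
    mode: Literal["abstract", "sequence"] = "abstract",
    sequences: Mapping[str, str] | None = None,
    read_length: int = 75,
    error_rate: float = 0.0,
    mean_fragment: int = DEFAULT_MEAN_FRAGMENT,
    depth_cap: int = SEQUENCE_MODE_DEPTH_CAP,
) -> ReadLibrary:
    """Simulate one library from the truth's expected proportions.

    Reads are i.i.d. draws from transcripts with probability proportional
    to abundance times effective length; read starts are uniform along the
    transcript.  Abstract mode returns exact multinomial per-transcript
    counts (summing to ``depth``) without synthesising sequence; sequence
    mode (capped at ``depth_cap`` reads) emits reads, optionally with a
    uniform substitution error rate.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    q = _sampling_probs(truth, sample, mean_fragment)
    rng = stream(seed, "simulate", sample.sample_id)
    if mode == "abstract":
        counts = rng.multinomial(depth, q.to_numpy())
        return ReadLibrary(sample_id=sample.sample_id, counts=pd.Series(counts, index=q.index),
                           read_length=read_length)
    if depth > depth_cap:
        raise ValueError(f"sequence-mode depth {depth} exceeds the safety cap {depth_cap}")
    if sequences is None:
        raise ValueError("sequence mode needs transcript sequences")
    missing = [g for g in q.index if g not in sequences]
    if missing:
        raise KeyError(f"transcripts without sequence: {missing[:5]}")
    tx_ids = list(q.index)
    picks = rng.choice(len(tx_ids), size=depth, p=q.to_numpy())
    reads: list[str] = []
    bases = np.array(list("ACGT"))
    for t in picks:
        seq = sequences[tx_ids[t]]
        span = min(read_length, len(seq))
        start = int(rng.integers(0, len(seq) - span + 1))
        read = seq[start : start + span]
        if error_rate > 0:
            arr = np.array(list(read))
            hit = rng.random(span) < error_rate
            if hit.any():
                arr[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
                read = "".join(arr)
        reads.append(read)
    return ReadLibrary(sample_id=sample.sample_id, reads=reads, read_length=read_length)


# ---------------------------------------------------------------------------
# annotation / orthology / PPI fixtures


@dataclass
class AnnotationFixtures:
    """File-shaped fixtures spanning every annotation and PPI rule branch.

    ``annotation_truth`` and the ``expected_keep``/``reject_reason``
    columns of ``ppi_table`` record the hand-tabulated expected outcome of
    each rule cascade, for verification against the implementation.
    """

    hit_table: pd.DataFrame
    human_proteome_lengths: pd.DataFrame
    go_table: pd.DataFrame
    orthology_table: pd.DataFrame
    ppi_table: pd.DataFrame
    uniprot_map: pd.DataFrame
    hgnc_map: dict[str, str]
    annotation_truth: pd.DataFrame


def _hit_row(gene, subject_id, desc, genus, ident, aln, gaps, ev, human=False, subj_len=None, qlen=200):
    return {
        "gene": gene, "subject_id": subject_id, "description": desc, "genus": genus,
        "percent_identity": ident, "alignment_length": aln, "gap_count": gaps,
        "e_value": ev, "is_human": human, "subject_protein_length": subj_len,
        "query_protein_length": qlen,
    }


def make_annotation_fixtures(genes: Sequence[str], seed: int = 0) -> AnnotationFixtures:
    """Build hit/GO/orthology/PPI fixtures over the given genes.

    Deterministic for a fixed seed.  The first nine genes exercise
    annotation categories 1-8 and 'unannotated'; orthology rows sit on
    both sides of every score threshold; PPI edges cover each rejection
    reason.  The GO table contains NAS- and ND-evidence rows and a term
    annotating fewer than 10 genes.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("non-empty gene list required")
    # the scenarios need 12 distinct genes; pad short lists with auxiliaries
    pad = 0
    while len(genes) < 12:
        genes.append(f"GFIX{pad:03d}")
        pad += 1

    def g(i: int) -> str:
        return genes[i]

    desc_named = "solute carrier family 2 member 1"
    hgnc_map = {desc_named: "SLC2A1"}
    rows: list[dict] = []
    truth: list[dict] = []
    # categories 1-4: human best hit + enough genera; graded by human coverage
    for cat, subj_len in zip((1, 2, 3, 4), (200, 240, 350, 520)):
        gene = g(cat - 1)
        rows.append(_hit_row(gene, f"HSA{cat:03d}", desc_named, "Homo", 95.0, 190, 0, 1e-80,
                             human=True, subj_len=subj_len))
        for j, genus in enumerate(("Mus", "Rattus", "Canis", "Sus")):
            rows.append(_hit_row(gene, f"OTH{cat:03d}{j}", desc_named, genus, 92.0, 185, 0, 1e-70))
        truth.append({"gene": gene, "expected_category": cat, "expected_name": "SLC2A1"})
    # category 5: 4+ genera and a human hit of unknown protein length
    gene5 = g(4)
    rows.append(_hit_row(gene5, "HSA005", desc_named, "Homo", 94.0, 188, 0, 1e-75, human=True))
    for j, genus in enumerate(("Mus", "Rattus", "Canis", "Sus")):
        rows.append(_hit_row(gene5, f"OTH005{j}", desc_named, genus, 91.0, 182, 0, 1e-66))
    truth.append({"gene": gene5, "expected_category": 5, "expected_name": "SLC2A1"})
    # category 6: human hit but only 3 non-Gallus genera
    gene6 = g(5)
    rows.append(_hit_row(gene6, "HSA006", "transferrin receptor protein", "Homo", 93.0, 186, 0,
                         1e-72, human=True, subj_len=200))
    for j, genus in enumerate(("Mus", "Rattus")):
        rows.append(_hit_row(gene6, f"OTH006{j}", "transferrin receptor protein", genus, 92.0, 184, 0, 1e-60))
    truth.append({"gene": gene6, "expected_category": 6, "expected_name": None})
    # category 7: high-quality hits, none human; a better-scoring
    # 'hypothetical' hit must be ignored by every category above 8
    gene7 = g(6)
    rows.append(_hit_row(gene7, "BAD007", "hypothetical protein LOC1", "Mus", 97.0, 195, 0, 1e-95))
    rows.append(_hit_row(gene7, "OTH007", "ferritin heavy chain", "Mus", 91.0, 183, 0, 1e-55))
    rows.append(_hit_row(gene7, "OTH008", "ferritin heavy chain", "Rattus", 90.0, 181, 0, 1e-52))
    truth.append({"gene": gene7, "expected_category": 7, "expected_name": None})
    # category 8: only a disqualified (hypothetical) description remains
    gene8 = g(7)
    rows.append(_hit_row(gene8, "BAD008", "hypothetical protein LOC2", "Mus", 96.0, 190, 0, 1e-60))
    truth.append({"gene": gene8, "expected_category": 8, "expected_name": None})
    # unannotated: nothing at or below the E-value cutoff
    gene9 = g(8)
    rows.append(_hit_row(gene9, "WEAK009", desc_named, "Mus", 80.0, 100, 1, 1e-10))
    truth.append({"gene": gene9, "expected_category": None, "expected_name": None})

    hit_table = pd.DataFrame(rows)
    human_lengths = (
        hit_table.loc[hit_table["is_human"] & hit_table["subject_protein_length"].notna(),
                      ["subject_id", "subject_protein_length"]]
        .rename(columns={"subject_protein_length": "length"})
        .reset_index(drop=True)
    )

    # GO table: one kept term (10 experimental genes), one term pushed under
    # the floor by its NAS rows (12 genes, 3 via NAS), one small term, ND rows
    go_rows = []
    for i in range(10):
        go_rows.append({"gene": g(i), "term": "GO:0001000", "evidence": "EXP"})
    for i in range(12):
        ev = "NAS" if i < 3 else "IDA"
        go_rows.append({"gene": g(i), "term": "GO:0002000", "evidence": ev})
    for i in range(5):
        go_rows.append({"gene": g(i), "term": "GO:0003000", "evidence": "IMP"})
    for i in range(4):
        go_rows.append({"gene": g(i), "term": "GO:0004000", "evidence": "ND"})
    go_table = pd.DataFrame(go_rows)

    # orthology: rows on both sides of each filter boundary
    ortho = pd.DataFrame(
        [
            ("HGENE01", "CGENE01", True, 1.0, 80.0, 90.0, 100.0),  # passes all
            ("HGENE02", "CGENE02", True, 1.0, 85.0, 88.0, 60.0),   # gene-order conservation 60 -> fail
            ("HGENE03", "CGENE03", True, 1.0, 74.0, 90.0, 80.0),   # reciprocal identity just under
            ("HGENE04", "CGENE04", True, 1.0, 75.0, 75.0, 75.0),   # exact boundary -> pass
            ("HGENE05", "CGENE05", True, 0.0, 90.0, 90.0, 90.0),   # confidence 0 -> fail
            ("HGENE06", "CGENE06", False, 1.0, 90.0, 90.0, 90.0),  # not one-to-one -> fail
            ("HGENE07", "CGENE07", True, 1.0, 92.0, 83.0, 79.0),   # passes all
        ],
        columns=["human_gene", "target_gene", "one2one", "confidence",
                 "recip_identity", "wga_score", "goc_score"],
    )

    uniprot_map = pd.DataFrame(
        [
            ("UP00001", "HGENE01"),
            ("UP00004", "HGENE04"),
            ("UP00007", "HGENE07"),
            ("UP00002", "HGENE02"),
            ("UP00005", "HGENE05"),
            ("UPAMBIG", "HGENE01"),
            ("UPAMBIG", "HGENE07"),
        ],
        columns=["uniprot", "human_gene"],
    )

    ppi = pd.DataFrame(
        [
            ("UP00001", "UP00004", "exp", True, ""),
            ("UP00001", "UP00007", "pred", True, ""),
            ("UP00004", "UP00007", "ortho", False, "evidence_not_exp_or_pred"),
            ("UPAMBIG", "UP00001", "exp", False, "ambiguous_uniprot"),
            ("UPMISSING", "UP00001", "exp", False, "unmapped_uniprot"),
            ("UP00002", "UP00001", "exp", False, "no_qualifying_orthologue"),
            ("UP00005", "UP00004", "pred", False, "no_qualifying_orthologue"),
            ("UP00004", "UP00001", "exp", False, "duplicate_pair"),
        ],
        columns=["uniprot_a", "uniprot_b", "evidence", "expected_keep", "reject_reason"],
    )

    return AnnotationFixtures(
        hit_table=hit_table,
        human_proteome_lengths=human_lengths,
        go_table=go_table,
        orthology_table=ortho,
        ppi_table=ppi,
        uniprot_map=uniprot_map,
        hgnc_map=hgnc_map,
        annotation_truth=pd.DataFrame(truth),
    )
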