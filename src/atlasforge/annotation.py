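"""Annotation-quality categories and orthology-mapped PPI overlay.

Genes lacking a curated name are annotated by transferring descriptions
from protein-alignment (blastp-style) hits, with each chosen annotation
graded into a quality category from 1 (best) to 8 (worst):

- 8: best hit (lowest E-value) of any kind — a description of last resort;
- 7: best *high-quality* hit, i.e. one with identity >= 90% in the aligned
  region, alignment length >= 90% of the query protein and >= 50 aa, and
  no gaps; hits described as low quality / hypothetical / unnamed /
  uncharacterized / putative, or carrying third-party annotation, never
  qualify;
- 6: as 7, with at least one high-quality hit to the human proteome;
- 5: as 6, with high-quality hits spanning at least 4 genera besides the
  query's own (Gallus);
- 1-4: as 5, graded by how much of the human protein the alignment covers
  (>= 90% -> 1, >= 75% -> 2, >= 50% -> 3, < 50% -> 4).

A gene symbol is transferred only when at least 75% of the qualifying
alignments agree on a (normalised) description that has a known HGNC
symbol.

Human protein-protein interactions are projected onto the target species
through one-to-one orthology: an interaction survives only if both
UniProt endpoints map unambiguously to one human gene, both human genes
have a one-to-one orthologue with orthology confidence 1 and reciprocal
identity, whole-genome alignment and gene-order conservation scores all
>= 75%, and the interaction evidence is experimental ('exp') or predicted
('pred') — never itself orthology-derived ('ortho').
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BlastHit",
    "AnnotationResult",
    "categorize_hits",
    "map_ppi",
    "intersect_ppi_clusters",
    "normalize_description",
    "EVALUE_CUTOFF",
]

EVALUE_CUTOFF = 1e-25
LOW_QUALITY_MARKERS = ("low quality", "hypothetical", "unnamed", "uncharacterized", "putative")
THIRD_PARTY_MARKERS = ("tpa:", "tpa_inf:", "third-party")
HIGH_QUALITY_IDENTITY = 90.0
HIGH_QUALITY_QUERY_FRACTION = 0.90
HIGH_QUALITY_MIN_AA = 50
NAME_AGREEMENT = 0.75
MIN_GENERA = 4
ORTHOLOGY_SCORE_FLOOR = 75.0

_ISOFORM_RE = re.compile(r"\s+(isoform|variant|transcript variant)\s+\S+$")


@dataclass(frozen=True)
class BlastHit:
    """One protein-alignment hit for a query gene."""

    subject_id: str
    description: str
    genus: str
    percent_identity: float
    alignment_length: int  # amino acids
    gap_count: int
    e_value: float
    is_human: bool = False
    subject_protein_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent identity outside [0, 100]")
        if self.e_value < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class AnnotationResult:
    gene_id: str
    description: str | None
    assigned_name: str | None
    category: int | None  # 1..8, or None = unannotated

    @property
    def label(self) -> str:
        return "unannotated" if self.category is None else str(self.category)


def normalize_description(desc: str) -> str:
    """Lowercase, collapse whitespace, strip isoform/variant suffixes."""
    d = re.sub(r"\s+", " ", desc.strip().lower())
    return _ISOFORM_RE.sub("", d)


def _is_low_quality(hit: BlastHit) -> bool:
    d = hit.description.lower()
    return any(m in d for m in LOW_QUALITY_MARKERS) or any(m in d for m in THIRD_PARTY_MARKERS)


def _hit_order(hit: BlastHit) -> tuple:
    # lowest E-value first; ties by higher identity, then subject id
    return (hit.e_value, -hit.percent_identity, hit.subject_id)


def categorize_hits(
    gene_id: str,
    hits: Sequence[BlastHit],
    query_protein_length: int,
    hgnc: Mapping[str, str] | None = None,
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> AnnotationResult:
    """Choose a description for a gene and grade its quality (1-8).

    ``query_protein_length`` is the length in amino acids of the gene's
    longest encoded peptide.  ``hgnc`` maps normalised descriptions to
    gene symbols.  Genes with no hit at or below the E-value cutoff are
    unannotated.  The >= 4 genera rule is counted over the high-quality
    hits (the qualifying alignment set), excluding Gallus.
    """
    usable = sorted((h for h in hits if h.e_value <= evalue_cutoff), key=_hit_order)
    if not usable:
        return AnnotationResult(gene_id, None, None, None)

    hq = [
        h
        for h in usable
        if h.percent_identity >= HIGH_QUALITY_IDENTITY
        and h.alignment_length >= HIGH_QUALITY_QUERY_FRACTION * query_protein_length
        and h.alignment_length >= HIGH_QUALITY_MIN_AA
        and h.gap_count == 0
        and not _is_low_quality(h)
    ]
    if not hq:
        best = usable[0]
        return AnnotationResult(gene_id, best.description, None, 8)

    best_hq = hq[0]
    category = 7
    human_hq = [h for h in hq if h.is_human]
    if human_hq:
        category = 6
        genera = {h.genus.lower() for h in hq if h.genus} - {"gallus", ""}
        if len(genera) >= MIN_GENERA:
            category = 5
            best_human = human_hq[0]
            if best_human.subject_protein_length:
                coverage = best_human.alignment_length / best_human.subject_protein_length
                if coverage >= 0.90:
                    category = 1
                elif coverage >= 0.75:
                    category = 2
                elif coverage >= 0.50:
                    category = 3
                else:
                    category = 4

    name = None
    if category <= 5 and hgnc:
        descs = [normalize_description(h.description) for h in hq]
        modal = max(set(descs), key=lambda d: (descs.count(d), d))
        if descs.count(modal) / len(descs) >= NAME_AGREEMENT and modal in hgnc:
            name = hgnc[modal]
    return AnnotationResult(gene_id, best_hq.description, name, category)


def hits_from_table(table: pd.DataFrame) -> dict[str, list[BlastHit]]:
    """Group an extended outfmt-6-like hit table into per-gene hit lists."""
    out: dict[str, list[BlastHit]] = {}
    for row in table.itertuples(index=False):
        spl = getattr(row, "subject_protein_length", None)
        out.setdefault(row.gene, []).append(
            BlastHit(
                subject_id=row.subject_id,
                description=row.description,
                genus=row.genus,
                percent_identity=float(row.percent_identity),
                alignment_length=int(row.alignment_length),
                gap_count=int(row.gap_count),
                e_value=float(row.e_value),
                is_human=bool(row.is_human),
                subject_protein_length=int(spl) if spl and not pd.isna(spl) else None,
            )
        )
    return out


def map_ppi(
    ppis: pd.DataFrame,
    orthology: pd.DataFrame,
    uniprot_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project human PPIs onto the target species through strict orthology.

    ``ppis``: columns ``uniprot_a``, ``uniprot_b``, ``evidence``.
    ``orthology``: ``human_gene``, ``target_gene``, ``one2one`` (bool),
    ``confidence``, ``recip_identity``, ``wga_score``, ``goc_score``.
    ``uniprot_map``: ``uniprot``, ``human_gene`` (several rows for one
    UniProt id mean an ambiguous assignment, which disqualifies it).

    Returns ``(kept, rejected)``; kept edges are deduplicated unordered
    target-gene pairs, rejected edges carry one reason code.
    """
    up_counts = uniprot_map.groupby("uniprot")["human_gene"].nunique()
    up_unique = uniprot_map.drop_duplicates("uniprot").set_index("uniprot")["human_gene"]

    ortho_ok: dict[str, str] = {}
    for row in orthology.itertuples(index=False):
        if (
            bool(row.one2one)
            and float(row.confidence) == 1.0
            and float(row.recip_identity) >= ORTHOLOGY_SCORE_FLOOR
            and float(row.wga_score) >= ORTHOLOGY_SCORE_FLOOR
            and float(row.goc_score) >= ORTHOLOGY_SCORE_FLOOR
        ):
            ortho_ok[str(row.human_gene)] = str(row.target_gene)

    def resolve(uniprot: str) -> tuple[str | None, str]:
        if uniprot not in up_counts.index:
            return None, "unmapped_uniprot"
        if up_counts[uniprot] > 1:
            return None, "ambiguous_uniprot"
        human = up_unique[uniprot]
        target = ortho_ok.get(human)
        if target is None:
            return None, "no_qualifying_orthologue"
        return target, ""

    kept_rows, rejected_rows = [], []
    seen_pairs: set[tuple[str, str]] = set()
    for row in ppis.itertuples(index=False):
        if row.evidence not in ("exp", "pred"):
            rejected_rows.append((row.uniprot_a, row.uniprot_b, row.evidence, "evidence_not_exp_or_pred"))
            continue
        ga, why_a = resolve(row.uniprot_a)
        if ga is None:
            rejected_rows.append((row.uniprot_a, row.uniprot_b, row.evidence, why_a))
            continue
        gb, why_b = resolve(row.uniprot_b)
        if gb is None:
            rejected_rows.append((row.uniprot_a, row.uniprot_b, row.evidence, why_b))
            continue
        pair = (min(ga, gb), max(ga, gb))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        kept_rows.append((row.uniprot_a, row.uniprot_b, row.evidence, pair[0], pair[1]))

    kept = pd.DataFrame(kept_rows, columns=["uniprot_a", "uniprot_b", "evidence", "gene_a", "gene_b"])
    rejected = pd.DataFrame(rejected_rows, columns=["uniprot_a", "uniprot_b", "evidence", "reason"])
    return kept, rejected


def intersect_ppi_clusters(
    ppi_edges: pd.DataFrame,
    clusters,
    correlations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """PPI edges whose two genes share a co-expression cluster.

    Per retained edge the cluster id is reported, and, when a correlation
    matrix is supplied, the expression correlation of the pair.
    """
    membership = clusters.membership()
    rows = []
    for row in ppi_edges.itertuples(index=False):
        ca = membership.get(row.gene_a)
        cb = membership.get(row.gene_b)
        if ca is None or ca != cb:
            continue
        corr = None
        if correlations is not None and row.gene_a in correlations.index and row.gene_b in correlations.index:
            corr = float(correlations.loc[row.gene_a, row.gene_b])
        rows.append({"cluster_id": ca, "gene_a": row.gene_a, "gene_b": row.gene_b,
                     "evidence": row.evidence, "correlation": corr})
    return pd.DataFrame(rows, columns=["cluster_id", "gene_a", "gene_b", "evidence", "correlation"])
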