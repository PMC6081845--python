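"""End-to-end orchestration of the synthetic meta-atlas pipeline.

Stages, in order: generate the two-source transcriptome, merge it into a
non-redundant reference, simulate libraries, down-sample every library to
the common depth, quantify (first pass), run Zipf QC, revise the
reference using only QC-passing samples, re-quantify (second and final
pass), aggregate to median TPM per BioProject per tissue, compute PEM,
build and cluster the gene co-expression graph, run GO enrichment per
cluster, assign annotation categories, and overlay orthology-mapped PPIs.
Exactly two quantification iterations are performed; every stage's output
is written as TSV (plus FASTA for references) and summarised in a JSON
manifest, and a rerun with the same configuration reproduces the outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import atlas as atlas_mod
from . import enrichment as enr
from . import io as aio
from . import network, synthetic, zipf
from .quant import ExpressionTable, build_index, downsample, gene_summarize, quantify
from .reference import ReferenceSet, dedupe_union, revise_transcriptome

__all__ = ["PipelineConfig", "PipelineResult", "sample_plan", "run_pipeline", "match_planted_clusters"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of a synthetic atlas run.

    Defaults follow the atlas protocol: common depth 10 million reads,
    k = 21, Zipf acceptance band [-1.2, -0.8], gene-graph threshold
    Pearson r >= 0.80, sample-graph threshold Spearman rho >= 0.82, MCL
    inflation 2.2, clusters reported at > 25 members; the promoter (CAGE)
    preset uses threshold 0.75, a 10 tagsPM activity floor and a
    10-member cluster floor.
    """

    seed: int = 17
    # synthetic cohort
    n_genes: int = 500
    n_tissues: int = 6
    n_bioprojects: int = 3
    replicates: int = 2
    n_clusters: int = 6
    cluster_size: int = 25
    fold_up: float = 8.0
    zipf_sigma: float = 0.25
    replicate_sigma: float = 0.25
    corrupt_samples: dict = field(default_factory=dict)  # sample_id -> rank exponent alpha
    # depths and quantification
    depth: int = 10_000_000
    raw_depth_factor: float = 1.5
    k: int = 21
    quant_mode: str = "abstract"
    iterations: int = 2
    # QC
    zipf_band: tuple = (-1.2, -0.8)
    tpm_floor: float = 5.0
    min_points: int = 10
    single_tissue_filter: bool = True
    # network
    gene_threshold: float = 0.80
    sample_threshold: float = 0.82
    inflation: float = 2.2
    min_cluster_report: int = 26
    # CAGE / promoter preset (applied when clustering a promoter matrix)
    cage_threshold: float = 0.75
    cage_tagspm_floor: float = 10.0
    cage_min_cluster: int = 10
    # enrichment
    enrich_alpha: float = 0.05
    enrich_min_fold: float = 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zipf_band"] = list(self.zipf_band)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["zipf_band"] = tuple(d["zipf_band"])
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference1: ReferenceSet
    reference2: ReferenceSet
    truth: synthetic.AtlasTruth
    zipf_fits: list
    failed_samples: list[str]
    gene_table: ExpressionTable       # final (iteration 2) gene-level TPM
    aggregated: ExpressionTable
    pem: atlas_mod.PEMTable
    gene_graph: network.CorrelationGraph
    clusters: network.ClusterSet
    cluster_summary: pd.DataFrame
    enrichment: pd.DataFrame
    annotation: pd.DataFrame
    ppi_kept: pd.DataFrame
    ppi_overlap: pd.DataFrame
    manifest: dict


def sample_plan(cfg: PipelineConfig) -> list[synthetic.SampleSpec]:
    """The cohort layout: every BioProject covers every tissue with
    ``replicates`` libraries; sample ids are ``BP.tissue.rN``."""
    specs = []
    tissues = [f"tissue{t:02d}" for t in range(cfg.n_tissues)]
    for b in range(cfg.n_bioprojects):
        bp = f"BPSYN{b:03d}"
        for tissue in tissues:
            for r in range(cfg.replicates):
                sid = f"{bp}.{tissue}.r{r}"
                specs.append(
                    synthetic.SampleSpec(
                        sample_id=sid,
                        tissue=tissue,
                        bioproject=bp,
                        zipf_alpha=cfg.corrupt_samples.get(sid),
                        replicate_sigma=cfg.replicate_sigma,
                    )
                )
    return specs


def _primary_transcripts(ref: ReferenceSet) -> dict[str, str]:
    """One expressed transcript per gene: curated source wins, then id order."""
    rank = {"ensembl": 0, "refseq_nm": 1, "refseq_xm": 2}
    best: dict[str, tuple] = {}
    for rec in ref.records:
        key = (rank[rec.source], rec.transcript_id)
        gene = rec.effective_gene_id
        if gene not in best or key < best[gene]:
            best[gene] = key
    return {gene: tx for gene, (_, tx) in best.items()}


def _write(df: pd.DataFrame, path: Path, index: bool = False, label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=label, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run the full synthetic pipeline and write all outputs to ``outdir``."""
    if cfg.iterations != 2:
        raise ValueError("the pipeline performs exactly two quantification iterations")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stage_counts: dict[str, int] = {}

    def stage(name: str, count: int) -> None:
        stage_counts[name] = count
        logger.info("stage %-22s n=%-8d t=%.1fs", name, count, time.perf_counter() - t0)

    # 1. transcriptome and reference (iteration 1)
    ens, rs = synthetic.make_transcriptome(cfg.n_genes, cfg.seed)
    aio.write_fasta(ens, out / "transcripts_ensembl.fasta")
    aio.write_fasta(rs, out / "transcripts_refseq.fasta")
    ref1 = dedupe_union(ens, rs)
    aio.write_fasta(ref1.records, out / "reference_iter1.fasta")
    stage("reference_iter1", len(ref1.records))

    # 2. expression truth over primary transcripts
    primary = _primary_transcripts(ref1)
    tx_ids = sorted(primary.values())
    lengths = {r.transcript_id: len(r.sequence) for r in ref1.records}
    truth = synthetic.make_truth(
        n_genes=len(tx_ids),
        seed=cfg.seed,
        n_tissues=cfg.n_tissues,
        n_clusters=cfg.n_clusters,
        cluster_size=cfg.cluster_size,
        fold_up=cfg.fold_up,
        zipf_sigma=cfg.zipf_sigma,
        gene_ids=tx_ids,
        lengths={t: lengths[t] for t in tx_ids},
    )
    stage("truth_transcripts", len(tx_ids))

    # 3. simulate, down-sample, quantify (iteration 1)
    specs = sample_plan(cfg)
    raw_depth = int(cfg.depth * cfg.raw_depth_factor)
    index1 = build_index(ref1.records, cfg.k, with_kmers=cfg.quant_mode == "sequence")
    libs = {}
    tables = []
    for spec in specs:
        lib = synthetic.simulate_library(truth, spec, raw_depth, cfg.seed, mode="abstract")
        lib = downsample(lib, cfg.depth, cfg.seed)
        libs[spec.sample_id] = lib
        tables.append(quantify(lib, index1))
    meta = pd.DataFrame(
        {
            "bioproject": [s.bioproject for s in specs],
            "tissue": [s.tissue for s in specs],
            "stage": [s.stage for s in specs],
        },
        index=[s.sample_id for s in specs],
    )
    tx_table1 = ExpressionTable.concat(tables, meta)
    gene_table1 = gene_summarize(tx_table1, ref1.tx2gene())
    stage("quantified_iter1", len(specs))

    # 4. Zipf QC on gene-level TPM
    fits = [
        zipf.fit_sample(
            gene_table1.values[sid].to_numpy(), sid,
            tpm_floor=cfg.tpm_floor, min_points=cfg.min_points, band=tuple(cfg.zipf_band),
        )
        for sid in gene_table1.sample_ids
    ]
    passed, failed = zipf.filter_samples(fits, tuple(cfg.zipf_band))
    failed_ids = [f.sample_id for f in failed]
    _write(zipf.report(fits), out / "zipf_qc.tsv")
    stage("zipf_failed", len(failed_ids))

    # 5. reference revision and final quantification
    ref2 = revise_transcriptome(
        ref1, tx_table1, failed_ids, single_tissue_filter=cfg.single_tissue_filter
    )
    aio.write_fasta(ref2.records, out / "reference_iter2.fasta")
    _write(ref2.exclusion_table(), out / "exclusions.tsv")
    pd.Series(ref2.tx2gene(), name="gene_id").rename_axis("transcript_id").to_csv(
        out / "tx2gene.tsv", sep="\t"
    )
    stage("reference_iter2", len(ref2.records))

    index2 = build_index(ref2.records, cfg.k, with_kmers=cfg.quant_mode == "sequence")
    good_ids = [s.sample_id for s in specs if s.sample_id not in failed_ids]
    tables2 = [quantify(libs[sid], index2) for sid in good_ids]
    tx_table2 = ExpressionTable.concat(tables2, meta.loc[good_ids])
    gene_table = gene_summarize(tx_table2, ref2.tx2gene())
    aio.write_expression_tsv(gene_table, out / "gene_tpm_iter2.tsv")
    stage("quantified_iter2", len(good_ids))

    # 6. aggregation, PEM, networks
    agg = atlas_mod.aggregate(gene_table)
    aio.write_expression_tsv(agg, out / "atlas_aggregated.tsv")
    pem_table = atlas_mod.pem(agg)
    pem_table.values.to_csv(out / "pem.tsv", sep="\t", index_label="gene_id", float_format="%.6g")

    corr = atlas_mod.correlation_matrix(agg, axis="genes", method="pearson")
    graph = network.build_graph(corr, cfg.gene_threshold)
    edges = nx_edges_frame(graph)
    _write(edges, out / "gene_graph_edges.tsv")
    clusters = network.mcl(graph, cfg.inflation)
    clusters.membership().rename_axis("gene_id").to_csv(out / "clusters.tsv", sep="\t")
    summary = network.cluster_report(clusters, pem_table, cfg.min_cluster_report)
    _write(summary, out / "cluster_report.tsv")
    stage("gene_graph_edges", graph.n_edges())
    stage("clusters", len(clusters.clusters))

    sample_corr = atlas_mod.correlation_matrix(gene_table, axis="samples", method="spearman")
    sample_graph = network.build_graph(sample_corr, cfg.sample_threshold)
    _write(nx_edges_frame(sample_graph), out / "sample_graph_edges.tsv")

    # 7. enrichment over cluster gene sets (synthetic GO reference)
    atlas_genes = sorted(gene_table.feature_ids)
    fixtures = synthetic.make_annotation_fixtures(atlas_genes, cfg.seed)
    go_ref = enr.prepare_go(fixtures.go_table)
    universe = sorted(set(atlas_genes) & set(go_ref.genes()))
    enrich_rows = []
    for cid, members in clusters.clusters.items():
        study = sorted(set(members) & set(universe))
        if not study or not universe:
            continue
        for res in enr.fisher_enrich(study, universe, go_ref, cfg.enrich_alpha, cfg.enrich_min_fold):
            row = res.to_row()
            row["cluster_id"] = cid
            enrich_rows.append(row)
    enrich_df = pd.DataFrame(
        enrich_rows, columns=["cluster_id", "term", "observed", "expected", "fold", "p_value", "reported"]
    )
    _write(enrich_df, out / "enrichment.tsv")

    # 8. annotation categories and PPI overlay
    per_gene_hits = ann.hits_from_table(fixtures.hit_table)
    qlens = fixtures.hit_table.drop_duplicates("gene").set_index("gene")["query_protein_length"]
    ann_rows = []
    for gene in sorted(per_gene_hits):
        res = ann.categorize_hits(gene, per_gene_hits[gene], int(qlens[gene]), fixtures.hgnc_map)
        ann_rows.append(
            {"gene": gene, "name": res.assigned_name or "", "description": res.description or "",
             "category": res.label}
        )
    ann_df = pd.DataFrame(ann_rows, columns=["gene", "name", "description", "category"])
    _write(ann_df, out / "annotation.tsv")

    ppi_in = fixtures.ppi_table[["uniprot_a", "uniprot_b", "evidence"]]
    ppi_kept, ppi_rej = ann.map_ppi(ppi_in, fixtures.orthology_table, fixtures.uniprot_map)
    _write(ppi_kept, out / "ppi_mapped.tsv")
    _write(ppi_rej, out / "ppi_rejected.tsv")
    overlap = ann.intersect_ppi_clusters(ppi_kept, clusters, corr)
    _write(overlap, out / "ppi_cluster_overlap.tsv")
    stage("ppi_kept", len(ppi_kept))

    manifest = {
        "package": "atlasforge",
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "iterations": 2,
        "stage_counts": stage_counts,
        "samples": [s.sample_id for s in specs],
        "failed_samples": failed_ids,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        config=cfg, reference1=ref1, reference2=ref2, truth=truth, zipf_fits=fits,
        failed_samples=failed_ids, gene_table=gene_table, aggregated=agg, pem=pem_table,
        gene_graph=graph, clusters=clusters, cluster_summary=summary, enrichment=enrich_df,
        annotation=ann_df, ppi_kept=ppi_kept, ppi_overlap=overlap, manifest=manifest,
    )


def nx_edges_frame(cgraph: network.CorrelationGraph) -> pd.DataFrame:
    rows = [
        {"node_a": min(u, v), "node_b": max(u, v), "weight": float(d["weight"])}
        for u, v, d in cgraph.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).sort_values(
        ["node_a", "node_b"], ignore_index=True
    )


def match_planted_clusters(result: PipelineResult) -> pd.DataFrame:
    """Score recovery of the planted tissue-specific clusters.

    Each planted cluster (a transcript set, converted to gene ids) is
    matched to the inferred cluster containing the largest share of its
    members; recovery holds when that cluster's modal top-PEM tissue
    equals the planted tissue.
    """
    tx2gene = result.reference2.tx2gene()
    tx2gene1 = result.reference1.tx2gene()
    membership = result.clusters.membership()
    rows = []
    for pc in result.truth.planted_clusters.values():
        genes = {tx2gene.get(t, tx2gene1.get(t, t)) for t in pc.genes}
        genes &= set(membership.index)
        if not genes:
            rows.append({"planted": pc.cluster_id, "matched_cluster": None, "overlap": 0.0,
                         "planted_tissue": pc.tissues[0], "modal_tissue": None, "recovered": False})
            continue
        counts = membership.loc[sorted(genes)].value_counts()
        best = int(counts.idxmax())
        members = result.clusters.clusters[best]
        fractions, _ = atlas_mod.top_pem_tissue(result.pem, members)
        modal = fractions.idxmax()
        rows.append(
            {
                "planted": pc.cluster_id,
                "matched_cluster": best,
                "overlap": float(counts.max() / len(pc.genes)),
                "planted_tissue": pc.tissues[0],
                "modal_tissue": modal,
                "recovered": bool(modal == pc.tissues[0]),
            }
        )
    return pd.DataFrame(rows)
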