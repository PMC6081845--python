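"""Meta-atlas aggregation, tissue specificity (PEM) and correlation.

Replicate libraries are collapsed to one expression value per study
(BioProject) per tissue — the median TPM over replicates — so that no
single deeply-replicated study dominates the atlas.  Tissue specificity is
scored with the preferential expression measure

    PEM(g, t) = S - A,

where S is the gene's log2 expression in tissue t and A its mean log2
expression over all tissues, after clamping TPM below 1 (noise level) to 1
so that undetectable genes score 0 everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .quant import ExpressionTable

__all__ = [
    "PEMTable",
    "aggregate",
    "pem",
    "top_pem_tissue",
    "correlation_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class PEMTable:
    """Genes x tissues matrix of preferential expression (log2 units)."""

    values: pd.DataFrame  # rows: genes, columns: tissues

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)


def aggregate(table: ExpressionTable) -> ExpressionTable:
    """Collapse replicate samples to median TPM per (BioProject, tissue).

    Column labels of the result encode both keys as ``BIOPROJECT.tissue``;
    the result's metadata records the two keys separately.  The median of
    an even replicate count is the mean of the central pair.
    """
    meta = table.meta
    for col in ("bioproject", "tissue"):
        if col not in meta.columns or meta[col].isna().any():
            raise ValueError(f"every sample needs a '{col}' label")
    groups = meta.groupby(["bioproject", "tissue"], sort=True).groups
    cols = {}
    new_meta = []
    for (bp, tissue), samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"group {bp}/{tissue} has zero replicates")
        label = f"{bp}.{tissue}"
        cols[label] = table.values[list(samples)].median(axis=1)
        new_meta.append({"column": label, "bioproject": bp, "tissue": tissue, "n_replicates": len(samples)})
    values = pd.DataFrame(cols)
    meta_df = pd.DataFrame(new_meta).set_index("column")
    return ExpressionTable(values, table.level, meta_df.loc[values.columns])


def _tissue_medians(agg: ExpressionTable) -> pd.DataFrame:
    """Collapse BioProject x tissue columns to one column per tissue."""
    return agg.values.T.groupby(agg.meta["tissue"]).median().T


def pem(agg: ExpressionTable) -> PEMTable:
    """Preferential expression measure per gene per tissue.

    Aggregated columns are first collapsed to a single value per tissue
    (median over BioProjects), TPM below 1 is clamped to 1, values are
    log2-transformed, and each gene's mean over tissues is subtracted.
    Rows therefore sum to zero; genes never detected (all TPM < 1) are 0
    in every tissue.
    """
    by_tissue = _tissue_medians(agg)
    logged = np.log2(by_tissue.clip(lower=1.0))
    centred = logged.sub(logged.mean(axis=1), axis=0)
    return PEMTable(centred)


def top_pem_tissue(
    pem_table: PEMTable, gene_set: Iterable[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """For a gene set, the fraction of genes peaking in each tissue.

    Returns ``(fractions, per_gene)``: a per-tissue fraction series over
    the gene set, and a per-gene table with the argmax tissue and a tie
    flag (ties broken lexicographically).
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in pem_table.values.index]
    if missing:
        raise KeyError(f"genes absent from PEM table: {missing[:5]}")
    sub = pem_table.values.loc[genes]
    # columns sorted so idxmax's first-wins rule is the lexicographic tie-break
    ordered = sub[sorted(sub.columns)]
    top = ordered.idxmax(axis=1)
    row_max = ordered.max(axis=1)
    tied = (ordered.eq(row_max, axis=0).sum(axis=1) > 1)
    per_gene = pd.DataFrame({"top_tissue": top, "tie": tied})
    fractions = top.value_counts(normalize=True).reindex(pem_table.tissue_ids, fill_value=0.0)
    return fractions, per_gene


def correlation_matrix(
    agg: ExpressionTable,
    axis: Literal["genes", "samples"] = "genes",
    method: Literal["pearson", "spearman"] = "pearson",
    log2_transform: bool = False,
) -> pd.DataFrame:
    """All-against-all correlation over genes (rows) or samples (columns).

    Gene-axis correlations are computed on the aggregated TPM as given (an
    optional log2(x+1) transform is exposed).  Constant profiles have no
    defined correlation; their entries are NaN (absent), never 0, and a
    warning names them.
    """
    data = agg.values
    if log2_transform:
        data = np.log2(data + 1.0)
    frame = data.T if axis == "genes" else data
    if axis == "genes" and frame.shape[0] < 3:
        raise ValueError("gene-axis correlation needs at least 3 aggregated columns")
    constant = frame.columns[frame.nunique() <= 1]
    if len(constant):
        logger.warning("%d constant profiles have undefined correlations", len(constant))
    corr = frame.corr(method=method)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr.values, [1.0 if c not in constant else np.nan for c in corr.columns])
    return corr
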