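"""GO term enrichment with curated-reference filters.

The reference annotation is filtered before any testing: annotations with
evidence codes NAS (non-traceable author statement) or ND (no biological
data) are dropped first, then terms left with fewer than 10 annotated
genes.  Enrichment of a study set against a universe is scored with the
one-sided (upper-tail) hypergeometric test; a term is *reported* only when
p < 0.05 and the observed count is at least twice the expected count.  An
optional elim-style mode removes the genes of significant child terms from
their ancestors before the ancestors are tested, decorrelating the nested
term structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GOReference",
    "EnrichmentResult",
    "prepare_go",
    "fisher_enrich",
    "elim_enrich",
]

logger = logging.getLogger(__name__)

EXCLUDED_EVIDENCE = ("NAS", "ND")
MIN_TERM_GENES = 10


@dataclass
class GOReference:
    """Filtered term -> gene-set map, optionally with parent links."""

    terms: dict[str, frozenset[str]]
    parents: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.terms.values():
            out |= s
        return frozenset(out)


@dataclass
class EnrichmentResult:
    term: str
    observed: int
    expected: float
    fold: float
    p_value: float
    reported: bool

    def to_row(self) -> dict:
        return {
            "term": self.term,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "p_value": self.p_value,
            "reported": self.reported,
        }


def prepare_go(
    annotations: pd.DataFrame,
    parents: Mapping[str, Iterable[str]] | None = None,
    excluded_evidence: tuple[str, ...] = EXCLUDED_EVIDENCE,
    min_genes: int = MIN_TERM_GENES,
) -> GOReference:
    """Build the filtered GO reference from (gene, term, evidence) rows.

    The evidence-code filter runs before the term-size filter, so a term
    losing members to the code filter can fall under the size floor.
    Malformed rows (missing fields) are logged and skipped.
    """
    required = {"gene", "term", "evidence"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    bad = annotations[list(required)].isna().any(axis=1)
    if bad.any():
        logger.warning("skipping %d malformed annotation rows", int(bad.sum()))
    rows = annotations[~bad]
    rows = rows[~rows["evidence"].isin(excluded_evidence)]
    terms: dict[str, frozenset[str]] = {}
    for term, grp in rows.groupby("term"):
        genes = frozenset(grp["gene"])
        if len(genes) >= min_genes:
            terms[str(term)] = genes
    par = {c: frozenset(p) for c, p in (parents or {}).items()}
    return GOReference(terms=terms, parents=par)


def _hypergeom_p(observed: int, universe_n: int, term_n: int, study_n: int) -> float:
    """Upper-tail hypergeometric: P(X >= observed)."""
    return float(stats.hypergeom.sf(observed - 1, universe_n, term_n, study_n))


def _one_term(
    term: str, term_genes: frozenset[str], study: frozenset[str], universe: frozenset[str],
    alpha: float, min_fold: float,
) -> EnrichmentResult:
    tg = term_genes & universe
    observed = len(tg & study)
    expected = len(study) * len(tg) / len(universe)
    p = _hypergeom_p(observed, len(universe), len(tg), len(study))
    fold = observed / expected if expected > 0 else 0.0
    return EnrichmentResult(term, observed, expected, fold, p, p < alpha and fold >= min_fold)


def fisher_enrich(
    study_set: Iterable[str],
    universe: Iterable[str],
    ref: GOReference,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    benjamini_hochberg: bool = False,
) -> list[EnrichmentResult]:
    """Classic one-sided hypergeometric enrichment, term by term.

    Reporting follows the raw p < ``alpha`` and fold >= ``min_fold`` rule;
    a Benjamini-Hochberg option re-evaluates the p criterion on adjusted
    p-values (off by default, matching the raw-p reporting convention).
    """
    study = frozenset(study_set)
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    if not study <= uni:
        raise ValueError("study set must be a subset of the universe")
    results = [
        _one_term(term, genes, study, uni, alpha, min_fold)
        for term, genes in sorted(ref.terms.items())
    ]
    if benjamini_hochberg:
        _apply_bh(results, alpha, min_fold)
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def _apply_bh(results: list[EnrichmentResult], alpha: float, min_fold: float) -> None:
    m = len(results)
    order = np.argsort([r.p_value for r in results], kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):  # largest p first
        i = order[rank - 1]
        running = min(running, results[i].p_value * m / rank)
        adj[i] = running
    for r, q in zip(results, adj):
        r.p_value = float(q)
        r.reported = q < alpha and r.fold >= min_fold


def elim_enrich(
    study_set: Iterable[str],
    universe: Iterable[str],
    ref: GOReference,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> list[EnrichmentResult]:
    """Elim-style decorrelated enrichment.

    Terms are tested leaves-first (children before parents, using the
    reference's parent links); when a term is significant its annotated
    genes are removed from every ancestor's gene set before that ancestor
    is tested.  Without any hierarchy this reduces exactly to
    :func:`fisher_enrich`.  A cyclic term graph is an error.
    """
    study = frozenset(study_set)
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    if not study <= uni:
        raise ValueError("study set must be a subset of the universe")

    # leaves first: a parent depends on (is preceded by) its children
    deps: dict[str, set[str]] = {t: set() for t in ref.terms}
    for child in ref.terms:
        for parent in ref.parents.get(child, ()):  # may include filtered-out terms
            if parent in deps:
                deps[parent].add(child)
    ts = TopologicalSorter(deps)
    try:
        order = list(ts.static_order())
    except CycleError as exc:
        raise ValueError("cyclic term hierarchy") from exc

    ancestors: dict[str, set[str]] = {}

    def collect_ancestors(t: str) -> set[str]:
        if t not in ancestors:
            out: set[str] = set()
            for p in ref.parents.get(t, ()):  # may include terms filtered out
                if p in ref.terms:
                    out |= {p} | collect_ancestors(p)
            ancestors[t] = out
        return ancestors[t]

    removed: dict[str, set[str]] = {t: set() for t in ref.terms}
    results: list[EnrichmentResult] = []
    for term in order:
        genes = frozenset(ref.terms[term] - removed[term])
        res = _one_term(term, genes, study, uni, alpha, min_fold)
        results.append(res)
        if res.p_value < alpha:
            for anc in collect_ancestors(term):
                removed[anc] |= set(ref.terms[term])
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
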