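"""Seeded down-sampling and k-mer based TPM quantification.

To make libraries sequenced at different depths comparable, every library
is first down-sampled (without replacement, seeded) to a common depth;
libraries below that depth are rejected.  Expression is then quantified at
the transcript level by pseudo-alignment: reads are assigned to the
equivalence class of transcripts compatible with their k-mers, class
counts are resolved to transcript counts by expectation-maximisation, and
abundances reported as transcripts per million,

    TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6,

with ``l`` the effective length (transcript length minus mean fragment
length plus one, floored at 1).  An "abstract-read" mode skips sequence
handling entirely and quantifies from true per-transcript read counts,
which is exact and fast for large simulated depths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .reference import TranscriptRecord

__all__ = [
    "ExpressionTable",
    "KmerIndex",
    "InsufficientDepthError",
    "downsample",
    "choose_k",
    "build_index",
    "quantify",
    "gene_summarize",
]

TPM_TOTAL = 1e6
DEFAULT_MEAN_FRAGMENT = 100  # single-end fragment-length assumption (-l 100)


class InsufficientDepthError(ValueError):
    """Raised when a library holds fewer reads than the requested depth."""

    reason = "insufficient_depth"


def effective_length(length: int, mean_fragment: int = DEFAULT_MEAN_FRAGMENT) -> float:
    return float(max(length - mean_fragment + 1, 1))


@dataclass
class ExpressionTable:
    """A features x samples TPM matrix with per-sample metadata.

    ``meta`` is indexed by sample id and carries at least ``bioproject``,
    ``tissue`` and ``stage`` for atlas-bound tables; single-sample
    quantifier output may leave them blank.
    """

    values: pd.DataFrame
    level: Literal["transcript", "gene"] = "transcript"
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(self.values[list(samples)], self.level, self.meta.loc[list(samples)])

    def check_tpm_closure(self, tol: float = 1e-3) -> None:
        sums = self.values.sum(axis=0)
        bad = sums[(sums - TPM_TOTAL).abs() > tol]
        if len(bad):
            raise AssertionError(f"TPM columns not summing to 1e6: {dict(bad)}")

    @staticmethod
    def concat(tables: Sequence["ExpressionTable"], meta: pd.DataFrame | None = None) -> "ExpressionTable":
        values = pd.concat([t.values for t in tables], axis=1).fillna(0.0)
        levels = {t.level for t in tables}
        if len(levels) != 1:
            raise ValueError("cannot concatenate tables of mixed level")
        if meta is None:
            meta = pd.concat([t.meta for t in tables])
        return ExpressionTable(values, levels.pop(), meta.loc[values.columns])


def downsample(lib, n: int, seed: int):
    """Down-sample a read library to exactly ``n`` reads without replacement.

    Selection is deterministic for a fixed seed and preserves input read
    order.  Libraries smaller than ``n`` are rejected
    (:class:`InsufficientDepthError`), mirroring the rule that libraries
    below the common depth are not used.  Abstract-read libraries are
    down-sampled by a multivariate hypergeometric draw over their count
    vector, the exact distribution of seeded without-replacement sampling.
    """
    from .synthetic import ReadLibrary  # avoid import cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = stream(seed, "downsample", lib.sample_id)
    if lib.counts is not None:
        total = int(lib.counts.sum())
        if total < n:
            raise InsufficientDepthError(
                f"{lib.sample_id}: {total} reads < requested depth {n}"
            )
        if total == n:
            new_counts = lib.counts.copy()
        else:
            drawn = rng.multivariate_hypergeometric(
                lib.counts.to_numpy(dtype=np.int64), n, method="marginals"
            )
            new_counts = pd.Series(drawn, index=lib.counts.index)
        return ReadLibrary(
            sample_id=lib.sample_id, layout=lib.layout, counts=new_counts,
            read_length=lib.read_length,
        )
    reads = lib.reads
    if len(reads) < n:
        raise InsufficientDepthError(f"{lib.sample_id}: {len(reads)} reads < requested depth {n}")
    if len(reads) == n:
        keep = list(range(n))
    else:
        keep = sorted(rng.choice(len(reads), size=n, replace=False))
    return ReadLibrary(
        sample_id=lib.sample_id, layout=lib.layout,
        reads=[reads[i] for i in keep],
        mates=[lib.mates[i] for i in keep] if lib.mates is not None else None,
        read_length=lib.read_length,
    )


def choose_k(min_read_len: int, max_read_len: int, default: int = 21) -> int:
    """Choose the k-mer size for the index from the read-length range.

    The target interval is [max_read_len / 3, min_read_len / 2] — large
    enough to be specific, small enough that the error-prone 3' read tail
    does not break every k-mer.  Returns the odd integer nearest the
    interval midpoint (ties broken downward, favouring sensitivity); if
    the interval is empty the configured default (21) is returned.
    """
    if min_read_len <= 0 or max_read_len <= 0:
        raise ValueError("read lengths must be positive")
    if min_read_len > max_read_len:
        raise ValueError("min_read_len > max_read_len")
    lo, hi = max_read_len / 3.0, min_read_len / 2.0
    if lo > hi:
        return default
    mid = (lo + hi) / 2.0
    below = int(math.floor(mid))
    if below % 2 == 0:
        below -= 1
    above = below + 2
    return below if (mid - below) <= (above - mid) else above


@dataclass
class KmerIndex:
    """Map from k-mer to the set of transcripts containing it."""

    k: int
    kmers: dict[str, frozenset[str]]
    lengths: dict[str, int]
    eff_lengths: dict[str, float]

    def __post_init__(self) -> None:
        if self.k < 11 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 11")
        short = [t for t, l in self.lengths.items() if l < self.k]
        if short:
            raise ValueError(f"transcripts shorter than k={self.k}: {short[:5]}")

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self.lengths)


def build_index(
    records: Iterable[TranscriptRecord],
    k: int = 21,
    mean_fragment: int = DEFAULT_MEAN_FRAGMENT,
    with_kmers: bool = True,
) -> KmerIndex:
    """Build a k-mer index over a reference transcriptome.

    k-mers containing N are not indexed; reads likewise contribute only
    their N-free k-mers.  ``with_kmers=False`` builds a lengths-only index
    sufficient for abstract-read quantification.
    """
    lengths: dict[str, int] = {}
    tmp: dict[str, set[str]] = {}
    for rec in records:
        lengths[rec.transcript_id] = len(rec.sequence)
        if not with_kmers:
            continue
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            tmp.setdefault(km, set()).add(rec.transcript_id)
    if not lengths:
        raise ValueError("empty index: no transcripts")
    eff = {t: effective_length(l, mean_fragment) for t, l in lengths.items()}
    return KmerIndex(k=k, kmers={km: frozenset(s) for km, s in tmp.items()}, lengths=lengths, eff_lengths=eff)


def _read_class(read: str, index: KmerIndex) -> frozenset[str] | None:
    """Equivalence class of transcripts compatible with a read's k-mers.

    Compatibility means containing every k-mer of the read that is present
    in the index at all; when no single transcript matches all such k-mers
    the class falls back to the transcripts matching the most k-mers.
    Returns None for reads with no matching k-mer.
    """
    k = index.k
    hits: list[frozenset[str]] = []
    for i in range(len(read) - k + 1):
        km = read[i : i + k]
        if "N" in km:
            continue
        s = index.kmers.get(km)
        if s is not None:
            hits.append(s)
    if not hits:
        return None
    common = frozenset.intersection(*hits)
    if common:
        return common
    votes: dict[str, int] = {}
    for s in hits:
        for t in s:
            votes[t] = votes.get(t, 0) + 1
    best = max(votes.values())
    return frozenset(t for t, v in votes.items() if v == best)


def _em_resolve(
    class_counts: Mapping[frozenset, float],
    txs: list[str],
    eff_len: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> np.ndarray:
    """Resolve equivalence-class counts to per-transcript counts by EM.

    Starts from uniform abundances; the E step splits each class count
    among its member transcripts in proportion to abundance over effective
    length; converges when the largest change in the abundance fractions
    (which sum to 1) falls below ``tol``.
    """
    idx = {t: i for i, t in enumerate(txs)}
    classes = [(np.fromiter((idx[t] for t in s), dtype=int), n) for s, n in class_counts.items()]
    total = sum(n for _, n in classes)
    if total == 0:
        return np.zeros(len(txs))
    alpha = np.full(len(txs), 1.0 / len(txs))
    for _ in range(max_iter):
        new_counts = np.zeros(len(txs))
        for members, n in classes:
            w = alpha[members] / eff_len[members]
            denom = w.sum()
            if denom <= 0:
                w = 1.0 / eff_len[members]
                denom = w.sum()
            new_counts[members] += n * w / denom
        new_alpha = new_counts / total
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha * total


def _tpm_from_counts(counts: np.ndarray, eff_len: np.ndarray) -> np.ndarray:
    rate = counts / eff_len
    denom = rate.sum()
    if denom == 0:
        return np.zeros_like(rate)
    return rate / denom * TPM_TOTAL


def quantify(lib, index: KmerIndex, max_iter: int = 200, tol: float = 1e-8) -> ExpressionTable:
    """Quantify one library against an index; returns a one-sample table.

    Sequence mode pseudo-aligns each read to its transcript equivalence
    class and resolves class counts by EM.  Abstract-read mode uses the
    library's true per-transcript counts directly (reads from transcripts
    absent from the index are counted as unmapped).  Reads shorter than k
    are skipped and counted.
    """
    txs = index.transcript_ids
    eff = np.array([index.eff_lengths[t] for t in txs])
    n_short = n_unmapped = 0
    if lib.counts is not None:
        aligned = lib.counts.reindex(txs).fillna(0.0)
        n_unmapped = int(lib.counts.sum() - aligned.sum())
        est = aligned.to_numpy(dtype=float)
    else:
        class_counts: dict[frozenset, float] = {}
        for read in lib.reads:
            if len(read) < index.k:
                n_short += 1
                continue
            cls = _read_class(read.upper(), index)
            if cls is None:
                n_unmapped += 1
                continue
            class_counts[cls] = class_counts.get(cls, 0.0) + 1.0
        est = _em_resolve(class_counts, txs, eff, max_iter=max_iter, tol=tol)
    tpm = _tpm_from_counts(est, eff)
    values = pd.DataFrame({lib.sample_id: tpm}, index=pd.Index(txs, name="transcript_id"))
    meta = pd.DataFrame(
        {
            "n_reads": [int(est.sum()) + n_unmapped + n_short],
            "n_unmapped": [n_unmapped],
            "n_too_short": [n_short],
        },
        index=[lib.sample_id],
    )
    return ExpressionTable(values, "transcript", meta)


def gene_summarize(tx_table: ExpressionTable, tx2gene: Mapping[str, str]) -> ExpressionTable:
    """Sum transcript TPM to gene level; per-sample totals are preserved."""
    if tx_table.level != "transcript":
        raise ValueError("input must be transcript-level")
    missing = [t for t in tx_table.feature_ids if t not in tx2gene]
    if missing:
        raise KeyError(f"transcripts without gene mapping: {missing[:5]}")
    genes = pd.Index([tx2gene[t] for t in tx_table.feature_ids], name="gene_id")
    values = tx_table.values.groupby(genes).sum()
    return ExpressionTable(values, "gene", tx_table.meta)
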