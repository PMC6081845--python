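"""Library quality control via Zipf's-law compliance.

In a well-prepared RNA-seq library a minority of genes account for the
majority of reads: the reverse cumulative distribution of TPM — for each
expression level, the number of genes at or above it — is approximately a
power law with exponent -1 on log-log axes.  Each sample's curve is fitted
by ordinary least squares after robustness trimming, and samples whose
exponent deviates from -1 by more than 20% (outside [-1.2, -0.8]) are
excluded from the atlas and from the next quantification iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ZipfFit",
    "DEFAULT_BAND",
    "reverse_cumulative",
    "fit_zipf",
    "filter_samples",
]

DEFAULT_BAND = (-1.2, -0.8)
DEFAULT_TPM_FLOOR = 5.0
DEFAULT_MIN_POINTS = 10


@dataclass
class ZipfFit:
    """OLS fit of log10(genes with TPM >= level) on log10(level)."""

    sample_id: str
    exponent: float
    intercept: float
    n_points_used: int
    r_squared: float
    passed: bool
    reason: str = ""

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "exponent": self.exponent,
            "r_squared": self.r_squared,
            "n_points": self.n_points_used,
            "passed": self.passed,
            "reason": self.reason,
        }


def reverse_cumulative(tpm) -> tuple[np.ndarray, np.ndarray]:
    """Unique TPM levels and, per level, the number of genes at or above it.

    Levels are strictly increasing; counts are strictly decreasing by
    construction (every level is attained by at least one gene).
    """
    x = np.asarray(tpm, dtype=float)
    if x.size == 0:
        raise ValueError("empty TPM vector")
    if (x < 0).any():
        raise ValueError("negative TPM values")
    srt = np.sort(x)
    levels = np.unique(srt)
    counts = x.size - np.searchsorted(srt, levels, side="left")
    return levels, counts


def fit_zipf(
    points: tuple[np.ndarray, np.ndarray],
    sample_id: str = "",
    tpm_floor: float = DEFAULT_TPM_FLOOR,
    min_points: int = DEFAULT_MIN_POINTS,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ZipfFit:
    """Fit the reverse-cumulative curve on log-log axes.

    Trimming, for robustness: levels below ``tpm_floor`` (default 5, where
    transcriptional noise dominates) are dropped, then all points in the
    lowest and the highest remaining log10 decade (a decade is
    floor(log10 level)).  If fewer than ``min_points`` survive the fit is
    indeterminate and the sample fails with reason ``unfittable``.
    """
    levels, counts = (np.asarray(p, dtype=float) for p in points)
    keep = levels >= tpm_floor
    levels, counts = levels[keep], counts[keep]
    if levels.size:
        decades = np.floor(np.log10(levels)).astype(int)
        inner = (decades > decades.min()) & (decades < decades.max())
        levels, counts = levels[inner], counts[inner]
    if levels.size < min_points:
        return ZipfFit(sample_id, math.nan, math.nan, int(levels.size), math.nan, False, "unfittable")
    res = stats.linregress(np.log10(levels), np.log10(counts))
    exponent = float(res.slope)
    lo, hi = band
    passed = lo <= exponent <= hi
    return ZipfFit(
        sample_id,
        exponent,
        float(res.intercept),
        int(levels.size),
        float(res.rvalue**2),
        passed,
        "" if passed else "exponent_out_of_band",
    )


def fit_sample(tpm, sample_id: str = "", **kwargs) -> ZipfFit:
    """Convenience: reverse-cumulate a TPM vector and fit it."""
    return fit_zipf(reverse_cumulative(tpm), sample_id=sample_id, **kwargs)


def filter_samples(
    fits: list[ZipfFit], band: tuple[float, float] = DEFAULT_BAND
) -> tuple[list[ZipfFit], list[ZipfFit]]:
    """Partition fits into (passed, failed) for the given exponent band.

    A sample fails iff its exponent lies outside the closed interval
    [band[0], band[1]] — i.e. deviates from the optimum of -1 by more than
    the tolerated fraction — or its fit was indeterminate.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band lower bound must be below upper bound (signed scale)")
    passed: list[ZipfFit] = []
    failed: list[ZipfFit] = []
    for fit in fits:
        ok = (not math.isnan(fit.exponent)) and lo <= fit.exponent <= hi
        fit.passed = ok
        if ok:
            fit.reason = ""
            passed.append(fit)
        else:
            if not fit.reason:
                fit.reason = "exponent_out_of_band"
            failed.append(fit)
    return passed, failed


def report(fits: list[ZipfFit]) -> pd.DataFrame:
    """Per-sample QC table (sample, exponent, r-squared, n points, verdict)."""
    return pd.DataFrame([f.to_row() for f in fits])
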