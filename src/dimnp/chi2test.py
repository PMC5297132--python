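"""Per-locus chi-squared test of homogeneity across n samples.

At every base the observed normalized counts a_1..a_n are laid against the
per-sample backgrounds b_1..b_n as a 2xn contingency table. Expected values
are the usual marginal products, the statistic is

    chi2 = sum_i [ (a_i - A_i)^2 / A_i + (b_i - B_i)^2 / B_i ],

and the P-value is the upper tail of the chi-square distribution with
v = n - 1 degrees of freedom — the homogeneity df of a 2xn table.

The statistic is scale-linear: chi2(c*a, c*b) = c * chi2(a, b). Applied to
mean-1 fold-change values it is therefore bounded near 1 and can never reach
genome-wide significance; ``call_chi2`` rescales both rows to the pooled mean
raw coverage so the test sees depth-equalised read counts, which is the scale
on which a fold-change of interest produces the small P-values a region
caller thresholds on (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .occupancy import BackgroundTrack, OccupancyProfile

__all__ = [
    "LocusTable",
    "LocusTestTrack",
    "expected_values",
    "chi2_statistic",
    "pvalue_from_chi2",
    "call_chi2",
    "P_FLOOR",
]

P_FLOOR = 1e-300  # keeps -log10(P) finite


@dataclass
class LocusTable:
    """Observed counts a_i and backgrounds b_i at one locus for n samples."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be 1-D vectors of equal length")
        if len(self.a) < 2:
            raise ValueError("need at least 2 samples")
        if np.any(self.a < 0) or np.any(self.b <= 0):
            raise ValueError("require a_i >= 0 and b_i > 0")

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass
class LocusTestTrack:
    """Per-base chi2 and P-value vectors for one chromosome."""

    chrom: str
    chi2: np.ndarray
    pvalue: np.ndarray
    df: int
    testable: np.ndarray

    def __len__(self) -> int:
        return len(self.pvalue)


def expected_values(table: LocusTable) -> tuple[np.ndarray, np.ndarray]:
    """Marginal expected values A_i, B_i of the 2xn table with rows (a, b).

    A_i = (a_i + b_i) * sum(a) / sum(a + b) and likewise for B_i; column and
    row sums are conserved. A locus with sum(a) = 0 has A = 0 everywhere and
    is handled by the caller as untestable.
    """
    col = table.a + table.b
    grand = col.sum()
    A = col * (table.a.sum() / grand)
    B = col * (table.b.sum() / grand)
    return A, B


def chi2_statistic(table: LocusTable) -> tuple[float, int]:
    """The homogeneity statistic and its degrees of freedom (n - 1).

    Returns (nan, df) when any expected value is zero (untestable locus);
    no exception is raised.
    """
    A, B = expected_values(table)
    df = table.n - 1
    if np.any(A == 0) or np.any(B == 0):
        return float("nan"), df
    stat = float(np.sum((table.a - A) ** 2 / A + (table.b - B) ** 2 / B))
    return stat, df


def pvalue_from_chi2(chi2: float | np.ndarray, df: int) -> float | np.ndarray:
    """Upper-tail chi-square probability, floored at 1e-300.

    Uses the survival function (regularized upper incomplete gamma), accurate
    for very small P.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    p = stats.chi2.sf(chi2, df)
    return np.maximum(p, P_FLOOR) if np.ndim(p) else float(max(p, P_FLOOR))


def call_chi2(
    profiles: Sequence[OccupancyProfile],
    backgrounds: Sequence[BackgroundTrack] | None = None,
    scale: float | str = "auto",
) -> LocusTestTrack:
    """Per-base chi-squared test across >= 2 samples on one chromosome.

    ``scale`` multiplies both rows of every locus table before testing.
    ``"auto"`` uses the pooled mean raw coverage (mean of the samples'
    ``raw_mean``), i.e. the statistic of depth-equalised read counts; pass 1.0
    to test the raw fold-change values.

    Bases where every sample observes zero, or that any sample flagged
    untestable under local normalization, get testable = False and P = 1.
    """
    if len(profiles) < 2:
        raise ValueError("multiple-sample comparison requires >= 2 samples")
    L = len(profiles[0])
    chrom = profiles[0].chrom
    if any(len(p) != L or p.chrom != chrom for p in profiles):
        raise ValueError("profiles must share one chromosome and equal length")
    if backgrounds is None:
        from .occupancy import background_for

        backgrounds = [background_for(p) for p in profiles]
    if len(backgrounds) != len(profiles):
        raise ValueError("one background per profile required")

    if scale == "auto":
        raw_means = [p.raw_mean for p in profiles]
        scale_val = float(np.nanmean(raw_means))
        if not np.isfinite(scale_val) or scale_val <= 0:
            scale_val = 1.0
    else:
        scale_val = float(scale)
        if scale_val <= 0:
            raise ValueError("scale must be positive")

    n = len(profiles)
    a = np.vstack([p.values for p in profiles]) * scale_val  # (n, L)
    b = np.array([bg.value for bg in backgrounds], dtype=float)[:, None] * scale_val
    if np.any(b <= 0):
        raise ValueError("backgrounds must be positive")

    testable = np.ones(L, dtype=bool)
    for p in profiles:
        testable &= p.testable
    ta = a.sum(axis=0)
    testable &= ta > 0

    col = a + b  # column totals (n, L)
    grand = col.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = col * (ta / grand)
        B = col * (b.sum() / grand)
        terms = (a - A) ** 2 / A + (b - B) ** 2 / B
        chi2 = np.where(testable, np.nansum(terms, axis=0), 0.0)
    # zero expected cells can only arise at untestable (all-zero) bases here,
    # but guard against accidental NaN propagation anyway
    bad = ~np.isfinite(chi2)
    if np.any(bad):
        testable = testable & ~bad
        chi2 = np.where(bad, 0.0, chi2)

    df = n - 1
    pvalue = stats.chi2.sf(chi2, df)
    pvalue = np.where(testable, np.maximum(pvalue, P_FLOOR), 1.0)
    chi2 = np.where(testable, chi2, 0.0)
    return LocusTestTrack(chrom=chrom, chi2=chi2, pvalue=pvalue, df=df, testable=testable)
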