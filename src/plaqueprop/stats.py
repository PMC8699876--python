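"""Agreement and uncertainty statistics for original-vs-perturbed runs.

Paired differences use the convention ``original − perturbed``; standard
deviations default to the population convention (divide by n).  Both are
switchable.  Limits of agreement follow Bland–Altman (mean ± 1.96 sd)
with the standard large-sample confidence interval for each limit,
half-width 1.96·sqrt(3 sd²/n).  Multi-stage uncertainty is chained in
quadrature: u = sqrt(sd² + u_prev²).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "PairedComparison",
    "BlandAltmanResult",
    "RelativeErrorSummary",
    "paired_stats",
    "bland_altman",
    "bland_altman_from_stats",
    "pearson_r",
    "relative_error",
    "max_relative_error",
    "relative_error_summary",
    "propagate_uncertainty",
]

SdConvention = Literal["population", "sample"]

Z95 = 1.96


def _ddof(sd_convention: SdConvention) -> int:
    if sd_convention == "population":
        return 0
    if sd_convention == "sample":
        return 1
    raise StatsError(f"unknown sd convention {sd_convention!r}")


@dataclass(frozen=True)
class PairedComparison:
    """Paired original/perturbed values; differences are original − perturbed
    unless ``flip_sign`` is set."""

    original: np.ndarray
    perturbed: np.ndarray
    flip_sign: bool = False

    def __post_init__(self) -> None:
        orig = np.asarray(self.original, dtype=float)
        pert = np.asarray(self.perturbed, dtype=float)
        if orig.shape != pert.shape or orig.ndim != 1:
            raise StatsError("original and perturbed must be 1-D of equal length")
        if orig.size < 2:
            raise StatsError("need at least 2 paired values")
        object.__setattr__(self, "original", orig)
        object.__setattr__(self, "perturbed", pert)

    @property
    def n(self) -> int:
        return self.original.size

    @property
    def differences(self) -> np.ndarray:
        d = self.original - self.perturbed
        return -d if self.flip_sign else d


def paired_stats(
    comp: PairedComparison, sd_convention: SdConvention = "population"
) -> tuple[float, float]:
    """Mean and standard deviation of the paired differences."""
    d = comp.differences
    return float(d.mean()), float(d.std(ddof=_ddof(sd_convention)))


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_low_lower: float
    ci_low_upper: float
    ci_high_lower: float
    ci_high_upper: float
    n: int | None


def bland_altman_from_stats(
    mean_diff: float, sd_diff: float, n: int | None = None
) -> BlandAltmanResult:
    """Limits of agreement from a printed (mean, sd) pair.

    The limits depend only on mean and sd; the confidence intervals of
    the limits additionally need n and are NaN when it is unknown.
    """
    if sd_diff < 0:
        raise StatsError("sd must be non-negative")
    low = mean_diff - Z95 * sd_diff
    high = mean_diff + Z95 * sd_diff
    if n is not None and n >= 2:
        half = Z95 * np.sqrt(3.0 * sd_diff**2 / n)
    else:
        half = np.nan
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=low,
        loa_high=high,
        ci_low_lower=low - half,
        ci_low_upper=low + half,
        ci_high_lower=high - half,
        ci_high_upper=high + half,
        n=n,
    )


def bland_altman(
    comp: PairedComparison, sd_convention: SdConvention = "population"
) -> BlandAltmanResult:
    """Bland–Altman limits of agreement for a paired comparison."""
    mean, sd = paired_stats(comp, sd_convention)
    return bland_altman_from_stats(mean, sd, comp.n)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise StatsError("pearson_r needs >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("correlation undefined for a zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def relative_error(original: float, perturbed: float) -> float:
    """Signed percentage difference 100·(perturbed − original)/original."""
    if original == 0:
        raise StatsError("relative error undefined for a zero original value")
    return 100.0 * (perturbed - original) / original


def max_relative_error(
    original: Sequence[float], perturbed: Sequence[float]
) -> tuple[float, int]:
    """Largest |relative error| across pairs, and the index attaining it."""
    orig = np.asarray(original, dtype=float)
    pert = np.asarray(perturbed, dtype=float)
    if np.any(orig == 0):
        raise StatsError("relative error undefined for zero original values")
    re = 100.0 * np.abs(pert - orig) / np.abs(orig)
    idx = int(np.argmax(re))
    return float(re[idx]), idx


@dataclass(frozen=True)
class RelativeErrorSummary:
    """Relative errors (%) of the min/max/mean summary statistics."""

    re_min: float
    re_max: float
    re_mean: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.re_min, self.re_max, self.re_mean)


def relative_error_summary(
    orig: tuple[float, float, float], pert: tuple[float, float, float]
) -> RelativeErrorSummary:
    """Elementwise percentage difference of (min, max, mean) statistics."""
    if any(o == 0 for o in orig):
        raise StatsError("relative error undefined for zero original statistics")
    re = [100.0 * (p - o) / o for o, p in zip(orig, pert)]
    return RelativeErrorSummary(*re)


def propagate_uncertainty(sd: float, u_prev: float) -> float:
    """Quadrature combination u = sqrt(sd² + u_prev²) of a level's spread
    with the previous level's uncertainty."""
    if sd < 0 or u_prev < 0:
        raise StatsError("sd and u_prev must be non-negative")
    return float(np.hypot(sd, u_prev))
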