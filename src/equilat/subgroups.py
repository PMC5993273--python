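"""Subgroup structure of laterality-index distributions: the two-normal
mixture bimodality criterion, equal-variance pretesting and pooled/Welch
two-sample comparisons of laterality strength.

The bimodality criterion treats the right- and left-biased LI groups as the
components of an equal-weight two-normal mixture.  With component moments
(mu1, sigma1) for the right group and (mu2, sigma2) for the left group, the
mixture is judged bimodal when

    S(sigma1/sigma2) * (sigma1 + sigma2) < mu1 - mu2

where S is the separation factor: the smallest mean separation (in units of
sigma1 + sigma2) at which an equal-weight two-normal mixture acquires a
second mode.  S(1) = 1, the classical equal-variance threshold of two
standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .individual import LateralityResult

__all__ = [
    "GroupMoments",
    "BimodalityAssessment",
    "TwoSampleComparison",
    "split_by_sign",
    "group_moments",
    "separation_factor",
    "assess_bimodality",
    "bonett_variance_test",
    "equal_variance_pretest",
    "two_sample_t",
]

#: sigma-ratio grid and separation factors for the equal-weight two-normal
#: mixture, digitized from the defining computation (bisection on the mean
#: separation at which the mixture density acquires a second mode).  The
#: factor is scale-symmetric, S(r) = S(1/r), so ratios above 1 are inverted
#: before lookup; values between grid points are linearly interpolated.
_SEPARATION_RATIOS = np.round(np.arange(0.05, 1.0001, 0.05), 2)
_SEPARATION_FACTORS = np.array(
    [
        0.2447, 0.4248, 0.5702, 0.6902, 0.7899,
        0.8731, 0.9423, 0.9995, 1.0461, 1.0835,
        1.1124, 1.1337, 1.1479, 1.1552, 1.1559,
        1.1497, 1.1361, 1.1136, 1.0782, 1.0000,
    ]
)


@dataclass(frozen=True)
class GroupMoments:
    """Size, mean and sample standard deviation (n-1 denominator) of a group
    of LI values."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a moments group needs at least two values")
        if self.sd < 0:
            raise ValueError("standard deviation cannot be negative")


@dataclass(frozen=True)
class BimodalityAssessment:
    group_r: GroupMoments
    group_l: GroupMoments
    sigma_ratio: float
    separation_factor: float
    lhs: float  # S * (sigma1 + sigma2)
    rhs: float  # mu1 - mu2
    is_bimodal: bool


@dataclass(frozen=True)
class TwoSampleComparison:
    t: float
    df: int
    p_value: float
    method: str  # "pooled" or "welch"
    pretest_p: float | None


def split_by_sign(
    results: Sequence[LateralityResult],
) -> tuple[list[LateralityResult], list[LateralityResult]]:
    """(right-biased, left-biased) groups; ambilateral horses join neither."""
    right = [r for r in results if r.li > 0]
    left = [r for r in results if r.li < 0]
    return right, left


def group_moments(li_values: Sequence[float]) -> GroupMoments:
    values = np.asarray(li_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    return GroupMoments(
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
    )


def separation_factor(sigma_ratio: float) -> float:
    """Separation factor S for an equal-weight two-normal mixture.

    ``sigma_ratio`` is sigma1/sigma2; by scale symmetry ratios above 1 are
    inverted first.  Linear interpolation on the tabulated grid; ratios
    below the grid raise (such mixtures need a vanishing separation scale
    and the linear table no longer applies).
    """
    if sigma_ratio <= 0:
        raise ValueError("sigma ratio must be positive")
    r = sigma_ratio if sigma_ratio <= 1 else 1.0 / sigma_ratio
    if r < _SEPARATION_RATIOS[0]:
        raise ValueError(
            f"sigma ratio {sigma_ratio:g} outside the tabulated range "
            f"[{_SEPARATION_RATIOS[0]}, {1 / _SEPARATION_RATIOS[0]:g}]"
        )
    return float(np.interp(r, _SEPARATION_RATIOS, _SEPARATION_FACTORS))


def assess_bimodality(
    group_r: GroupMoments, group_l: GroupMoments
) -> BimodalityAssessment:
    """Apply the mixture-separation criterion with group 1 = right-biased.

    The verdict is translation invariant (only mu1 - mu2 enters) and
    invariant under common positive rescaling of both groups.
    """
    sigma_ratio = group_r.sd / group_l.sd
    factor = separation_factor(sigma_ratio)
    lhs = factor * (group_r.sd + group_l.sd)
    rhs = group_r.mean - group_l.mean
    return BimodalityAssessment(
        group_r=group_r,
        group_l=group_l,
        sigma_ratio=sigma_ratio,
        separation_factor=factor,
        lhs=lhs,
        rhs=rhs,
        is_bimodal=bool(lhs < rhs),
    )


def bonett_variance_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Bonett's robust two-sample test of equal variances (two-sided p).

    Log-variance z test with a pooled kurtosis estimate computed about
    trimmed means (trim proportion 1/(2*sqrt(n - 4))), after Bonett (2006).
    The small-sample c(alpha) interval correction is omitted so that the
    p-value is closed-form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("Bonett's test needs at least five values per sample")
    num = 0.0
    den = 0.0
    for s in (x, y):
        trim = 1.0 / (2.0 * np.sqrt(len(s) - 4))
        tm = stats.trim_mean(s, trim)
        num += float(np.sum((s - tm) ** 4))
        den += float(np.sum((s - s.mean()) ** 2))
    if den == 0.0:
        return 1.0
    kurt = (len(x) + len(y)) * num / den**2
    se2 = sum((kurt - (n - 3) / n) / (n - 1) for n in (len(x), len(y)))
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 or v2 == 0.0:
        return 0.0
    z = (np.log(v1) - np.log(v2)) / np.sqrt(se2)
    return float(2.0 * stats.norm.sf(abs(z)))


def equal_variance_pretest(x: Sequence[float], y: Sequence[float]) -> float:
    """Equal-variance pretest p-value for selecting pooled vs Welch t.

    With at least 20 observations in both samples the Bonett procedure p is
    returned; below that, the smaller of the Bonett p and the
    median-centered Levene (Brown-Forsythe) p.  Two degenerate
    zero-variance samples give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs at least three values")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        warnings.warn("both samples have zero variance; pretest p set to 1")
        return 1.0
    bonett = bonett_variance_test(x, y) if min(len(x), len(y)) >= 5 else None
    if len(x) >= 20 and len(y) >= 20 and bonett is not None:
        return bonett
    levene = float(stats.levene(x, y, center="median").pvalue)
    return levene if bonett is None else min(bonett, levene)


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    pretest_alpha: float = 0.05,
) -> TwoSampleComparison:
    """Two-sided two-sample t test of mean difference x - y.

    ``method="auto"`` pools when the equal-variance pretest p is at least
    ``pretest_alpha`` and uses Welch otherwise.  The Welch-Satterthwaite df
    is truncated to an integer and the p-value evaluated at that integer df
    (matching how the study's software reports Welch results).
    """
    if method not in ("auto", "pooled", "welch"):
        raise ValueError("method must be auto, pooled or welch")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two values")

    pretest_p = None
    if method == "auto":
        pretest_p = equal_variance_pretest(x, y)
        method = "pooled" if pretest_p >= pretest_alpha else "welch"

    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if method == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        if se == 0.0:
            df = n1 + n2 - 2  # degenerate constant samples
        else:
            df_ws = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
            df = int(df_ws)  # truncated, not rounded
    if se == 0.0:
        t = 0.0
        p = 1.0
    else:
        t = float(diff / se)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TwoSampleComparison(
        t=t, df=int(df), p_value=p, method=method, pretest_p=pretest_p
    )
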