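"""Per-horse laterality: the laterality index, one-proportion tests and
significance classification.

The laterality index over a horse's repeated lead observations is

    LI = 100 * (n_R - n_L) / (n_R + n_L)

so +100 is fully right-preferent, -100 fully left-preferent and 0
ambilateral.  Each horse's L/R counts are tested against a fair coin with a
two-sided one-proportion test: the exact binomial test when the number of
observations is small, otherwise the normal-approximation z test (no
continuity correction).  The exact two-sided p doubles the smaller tail and
caps at 1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .cohort import FocalHorseRecord

__all__ = [
    "Classification",
    "ProportionTestResult",
    "LateralityResult",
    "laterality_index",
    "one_proportion_normal",
    "one_proportion_exact",
    "assess_horse",
    "assess_cohort",
    "median_li",
    "results_to_frame",
]

#: Default per-horse significance level.
DEFAULT_ALPHA = 0.05
#: Trial-count cutoff at or below which the exact test is used.
DEFAULT_EXACT_THRESHOLD = 25


class Classification(enum.Enum):
    """Per-horse laterality verdict at significance level alpha."""

    SIG_L = "S(L)"
    SIG_R = "S(R)"
    NONSIG_L = "L"
    NONSIG_R = "R"
    AMBI = "AMBI"


@dataclass(frozen=True)
class ProportionTestResult:
    """Two-sided one-proportion test of ``count`` successes in ``n`` trials.

    ``z`` is always the normal-approximation statistic, even when the
    p-value comes from the exact binomial test (matching how the study
    reported its per-horse table)."""

    n: int
    count: int
    p_hat: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float
    method: str  # "normal" or "exact"

    def __post_init__(self) -> None:
        if not 0 <= self.count <= self.n:
            raise ValueError("count must lie in [0, n]")


@dataclass(frozen=True)
class LateralityResult:
    horse_id: str
    n_left: int
    n_right: int
    li: float
    test: ProportionTestResult
    classification: Classification


def _validate_trial(count: int, n: int, p0: float) -> None:
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("null proportion must lie strictly inside (0, 1)")


def laterality_index(n_left: int, n_right: int) -> float:
    """Signed percentage preference for the right lead."""
    if n_left < 0 or n_right < 0:
        raise ValueError("counts must be non-negative")
    total = n_left + n_right
    if total == 0:
        raise ValueError("no observations")
    return 100.0 * (n_right - n_left) / total


def _normal_z(count: int, n: int, p0: float) -> float:
    return (count / n - p0) / math.sqrt(p0 * (1.0 - p0) / n)


def _wald_ci(count: int, n: int, level: float = 0.95) -> tuple[float, float]:
    p_hat = count / n
    half = stats.norm.ppf(0.5 + level / 2) * math.sqrt(p_hat * (1 - p_hat) / n)
    return p_hat - half, p_hat + half


def one_proportion_normal(count: int, n: int, p0: float = 0.5) -> ProportionTestResult:
    """Normal-approximation z test without continuity correction.

    p = 2 * Phi(-|z|); the 95% CI is the Wald interval p_hat +/- 1.96 * SE.
    """
    _validate_trial(count, n, p0)
    z = _normal_z(count, n, p0)
    ci_low, ci_high = _wald_ci(count, n)
    return ProportionTestResult(
        n=n,
        count=count,
        p_hat=count / n,
        z=z,
        p_value=2.0 * stats.norm.sf(abs(z)),
        ci_low=ci_low,
        ci_high=ci_high,
        method="normal",
    )


def one_proportion_exact(count: int, n: int, p0: float = 0.5) -> ProportionTestResult:
    """Exact binomial test; two-sided p doubles the smaller tail (capped at 1).

    The ``z`` field still carries the normal-approximation statistic so that
    exact rows remain directly comparable with normal rows.
    """
    _validate_trial(count, n, p0)
    lower = stats.binom.cdf(count, n, p0)
    upper = stats.binom.sf(count - 1, n, p0)
    p_value = min(1.0, 2.0 * min(lower, upper))
    ci_low, ci_high = _wald_ci(count, n)
    return ProportionTestResult(
        n=n,
        count=count,
        p_hat=count / n,
        z=_normal_z(count, n, p0),
        p_value=p_value,
        ci_low=ci_low,
        ci_high=ci_high,
        method="exact",
    )


def assess_horse(
    record: FocalHorseRecord,
    alpha: float = DEFAULT_ALPHA,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> LateralityResult:
    """Compute a horse's LI and classify it at level ``alpha``.

    The exact test is used when the number of observations is at most
    ``exact_threshold``, the normal approximation otherwise.  Significance
    uses p <= alpha (inclusive).
    """
    n_left, n_right = record.n_left, record.n_right
    n = n_left + n_right
    test_fn = one_proportion_exact if n <= exact_threshold else one_proportion_normal
    test = test_fn(n_right, n)
    li = laterality_index(n_left, n_right)
    if li == 0:
        classification = Classification.AMBI
    elif test.p_value <= alpha:
        classification = Classification.SIG_R if li > 0 else Classification.SIG_L
    else:
        classification = Classification.NONSIG_R if li > 0 else Classification.NONSIG_L
    return LateralityResult(
        horse_id=record.horse_id,
        n_left=n_left,
        n_right=n_right,
        li=li,
        test=test,
        classification=classification,
    )


def assess_cohort(
    records: Iterable[FocalHorseRecord],
    alpha: float = DEFAULT_ALPHA,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> list[LateralityResult]:
    return [assess_horse(r, alpha, exact_threshold) for r in records]


def median_li(results: Sequence[LateralityResult], side: str) -> float:
    """Sample median LI over the horses preferring ``side`` ("L" or "R").

    Ambilateral horses (LI = 0) belong to neither class.
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    values = sorted(
        r.li for r in results if (r.li < 0 if side == "L" else r.li > 0)
    )
    if not values:
        raise ValueError(f"no horses with a {side} preference")
    mid = len(values) // 2
    if len(values) % 2:
        return values[mid]
    return 0.5 * (values[mid - 1] + values[mid])


def results_to_frame(results: Sequence[LateralityResult], sexes=None) -> pd.DataFrame:
    """Per-horse results as a table mirroring the published layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "horse_id": r.horse_id,
                "sex": getattr(sexes, "get", lambda *_: None)(r.horse_id)
                if sexes is not None
                else None,
                "n_left": r.n_left,
                "n_right": r.n_right,
                "li": r.li,
                "z": r.test.z,
                "p_value": r.test.p_value,
                "method": r.test.method,
                "classification": r.classification.value,
            }
        )
    frame = pd.DataFrame(rows)
    if sexes is None:
        frame = frame.drop(columns=["sex"])
    return frame
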