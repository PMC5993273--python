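"""Population-level laterality: proportion tests over a cohort, L:R ratios,
binary-logit association tests and the one-way F test of LI on groups."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import Cohort, Lead, RaceStartObservation
from .individual import ProportionTestResult, one_proportion_normal

__all__ = [
    "AssociationResult",
    "AnovaResult",
    "SeparationError",
    "population_proportion_test",
    "lead_ratio",
    "fit_binary_logit",
    "anova_li_on_groups",
]

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Complete separation: the likelihood has no finite maximiser."""


@dataclass(frozen=True)
class AssociationResult:
    """Likelihood-ratio test of a single categorical predictor of lead choice.

    ``chi_square`` = 2 * (loglik_full - loglik_null) against the
    intercept-only model; ``coefficients`` are log-odds (response coded
    R = 1) per non-reference level."""

    chi_square: float
    df: int
    p_value: float
    coefficients: dict[str, float]
    odds_ratios: dict[str, float]
    reference_level: str


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def population_proportion_test(
    cohort: Cohort,
    filter: Callable[[RaceStartObservation], bool] | None = None,
    side_counted: str = "R",
    p0: float = 0.5,
) -> ProportionTestResult:
    """One-proportion z test (normal approximation) over a filtered cohort.

    Counts starts on ``side_counted`` among all starts passing ``filter``
    and tests against ``p0``.
    """
    if side_counted not in ("L", "R"):
        raise ValueError("side_counted must be 'L' or 'R'")
    observations = [o for o in cohort if filter is None or filter(o)]
    if not observations:
        raise ValueError("no observations left after filtering")
    target = Lead.RIGHT if side_counted == "R" else Lead.LEFT
    count = sum(1 for o in observations if o.lead is target)
    return one_proportion_normal(count, len(observations), p0)


def lead_ratio(n_left: int, n_right: int) -> float:
    """Ratio of left to right starts (the study's "L:R" headline figure)."""
    if n_right < 1:
        raise ValueError("right-lead count must be at least 1")
    if n_left < 0:
        raise ValueError("counts must be non-negative")
    return n_left / n_right


def _as_binary_response(response: Iterable) -> np.ndarray:
    coded = []
    for item in response:
        value = item.value if isinstance(item, Lead) else str(item).strip().upper()
        if value == "R":
            coded.append(1.0)
        elif value == "L":
            coded.append(0.0)
        else:
            raise ValueError(f"response values must be leads, got {item!r}")
    return np.asarray(coded)


def fit_binary_logit(
    response: Sequence,
    predictors: Sequence,
    reference_level: str | None = None,
    min_level_count: int = 2,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> AssociationResult:
    """Binary logistic regression of lead (R = 1) on one categorical predictor.

    Maximum likelihood via Newton/IRLS (log-likelihood tolerance ``tol``,
    at most ``maxiter`` iterations).  ``chi_square`` is the likelihood-ratio
    statistic against the intercept-only model with df = number of
    non-reference levels retained.  Levels observed fewer than
    ``min_level_count`` times are dropped with a logged warning (the study
    excluded its 12- and 13-year-olds this way).
    """
    y = _as_binary_response(response)
    levels = pd.Series([str(p) for p in predictors], dtype="object")
    if len(levels) != len(y):
        raise ValueError("response and predictors must have equal length")

    counts = levels.value_counts()
    thin = counts[counts < min_level_count].index.tolist()
    if thin:
        logger.warning(
            "dropping predictor level(s) with fewer than %d observations: %s",
            min_level_count,
            ", ".join(sorted(thin)),
        )
        keep = ~levels.isin(thin)
        y, levels = y[keep.to_numpy()], levels[keep].reset_index(drop=True)

    unique = sorted(levels.unique())
    if len(unique) < 2:
        raise ValueError("need at least two distinct predictor levels")
    if reference_level is None:
        reference_level = unique[0]
    elif reference_level not in unique:
        raise ValueError(f"reference level {reference_level!r} not observed")
    others = [lvl for lvl in unique if lvl != reference_level]

    design = pd.DataFrame({"const": np.ones(len(y))})
    for lvl in others:
        design[lvl] = (levels == lvl).astype(float)

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        try:
            full = sm.Logit(y, design).fit(
                method="newton", tol=tol, maxiter=maxiter, disp=0
            )
            null = sm.Logit(y, design[["const"]]).fit(
                method="newton", tol=tol, maxiter=maxiter, disp=0
            )
        except (
            PerfectSeparationError,
            PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as exc:
            raise SeparationError("separation detected") from exc
    for fit in (full, null):
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError(
                f"logit did not converge within {maxiter} iterations"
            )
    if np.max(np.abs(full.params)) > 50:
        raise SeparationError("separation detected (diverging coefficients)")

    chi_square = max(0.0, 2.0 * (full.llf - null.llf))
    df = len(others)
    coefficients = {lvl: float(full.params[lvl]) for lvl in others}
    return AssociationResult(
        chi_square=chi_square,
        df=df,
        p_value=float(stats.chi2.sf(chi_square, df)),
        coefficients=coefficients,
        odds_ratios={k: float(np.exp(v)) for k, v in coefficients.items()},
        reference_level=reference_level,
    )


def anova_li_on_groups(
    li_values: Sequence[float], groups: Sequence
) -> AnovaResult:
    """One-way fixed-effects F test of LI on categorical group labels.

    The untransformed LIs are used; for two groups F equals the square of
    the pooled-variance two-sample t.
    """
    values = np.asarray(li_values, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    if len(values) != len(labels):
        raise ValueError("values and groups must have equal length")
    unique = np.unique(labels)
    if len(unique) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in unique]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two values")

    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_between = len(unique) - 1
    df_within = len(values) - len(unique)
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ValueError("zero within-group variance")
    f = (ss_between / df_between) / ms_within
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_between,
        df_within=df_within,
        p_value=float(stats.f.sf(f, df_between, df_within)),
    )
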