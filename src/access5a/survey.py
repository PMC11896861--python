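"""Sampling and data-hygiene utilities for the accessibility survey.

Minimum sample size for estimating a proportion, the questionnaire
response rate, marginal multiple imputation of sparse gaps in Likert
tables, and demographic profile summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fce import ResponseTable

__all__ = [
    "SamplingSpec",
    "ImputationResult",
    "min_sample_size",
    "response_rate",
    "impute_missing",
    "respondent_summary",
    "pool_scores",
]


@dataclass(frozen=True)
class SamplingSpec:
    """Inputs of the large-population sample-size formula.

    ``k`` is the normal quantile for the chosen confidence level (1.96
    for 95%), ``p`` the anticipated proportion (0.5 is the conservative
    maximum-variance choice) and ``eps`` the allowable absolute error.
    """

    k: float = 1.96
    p: float = 0.5
    eps: float = 0.05

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"quantile k must be positive, got {self.k}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"anticipated proportion must lie in [0, 1], got {self.p}")
        if not (0.0 < self.eps < 1.0):
            raise ValueError(f"allowable error must lie in (0, 1), got {self.eps}")


def min_sample_size(spec: SamplingSpec | None = None, **kwargs) -> int:
    """Minimum sample size n = floor(k^2 * p * (1 - p) / eps^2).

    At the conventional k=1.96, p=0.5, eps=0.05 this yields 384. The
    floor (rather than ceiling) matches how the bound is usually quoted
    for these round inputs.
    """
    if spec is None:
        spec = SamplingSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SamplingSpec or keyword arguments, not both")
    return math.floor(spec.k**2 * spec.p * (1.0 - spec.p) / spec.eps**2)


def response_rate(valid: int, distributed: int) -> float:
    """Valid-questionnaire response rate, in percent."""
    if distributed <= 0 or valid < 0 or valid > distributed:
        raise ValueError(f"invalid counts: {valid} valid of {distributed} distributed")
    return 100.0 * valid / distributed


@dataclass
class ImputationResult:
    """Completed response tables plus a log of every imputed cell."""

    tables: list[ResponseTable]
    log: pd.DataFrame  # columns: imputation, respondent, column, value

    @property
    def m(self) -> int:
        return len(self.tables)


def impute_missing(
    responses: ResponseTable,
    m_imputations: int = 5,
    seed: int | None = None,
    max_missing: float = 0.05,
) -> ImputationResult:
    """Multiple imputation of missing Likert cells by marginal hot-deck draws.

    Each gap is filled by a draw from the observed grade distribution of
    its own column, independently in each of ``m_imputations`` completed
    tables; downstream analyses run per table and pool by averaging.
    Because the membership matrices that feed the evaluation depend only
    on marginal grade frequencies, marginal draws are a sufficient
    imputation model here. Refuses tables whose overall missing fraction
    exceeds ``max_missing`` (default 5%).
    """
    if m_imputations < 1:
        raise ValueError("m_imputations must be >= 1")
    frac = responses.missing_fraction
    if frac > max_missing:
        per_column = responses.scores.isna().mean()
        diagnostics = per_column[per_column > 0].round(4).to_dict()
        raise ValueError(
            f"missing fraction {frac:.4f} exceeds cap {max_missing}; "
            f"per-column missing rates: {diagnostics}"
        )
    gaps = responses.scores.isna()
    if not gaps.to_numpy().any():
        return ImputationResult(
            tables=[responses],
            log=pd.DataFrame(columns=["imputation", "respondent", "column", "value"]),
        )

    rng = np.random.default_rng(seed)
    tables: list[ResponseTable] = []
    log_rows: list[dict] = []
    for imp in range(m_imputations):
        filled = responses.scores.copy()
        for column in filled.columns[gaps.any(axis=0)]:
            observed = filled[column].dropna().to_numpy()
            if observed.size == 0:
                raise ValueError(f"column {column!r} is entirely missing; cannot impute")
            idx = filled.index[gaps[column]]
            draws = rng.choice(observed, size=len(idx))
            filled.loc[idx, column] = draws
            for respondent, value in zip(idx, draws):
                log_rows.append(
                    {"imputation": imp, "respondent": respondent, "column": column, "value": value}
                )
        tables.append(
            ResponseTable(
                scores=filled,
                demographics=responses.demographics,
                grade_values=responses.grade_values,
            )
        )
    return ImputationResult(tables=tables, log=pd.DataFrame(log_rows))


def respondent_summary(
    demographics: pd.DataFrame | ResponseTable,
    categories: Sequence[str] | None = None,
    allowed: dict[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Percentage breakdown of respondents per demographic category.

    Returns a long frame (category, value, percent) with percentages to
    2 decimals summing to ~100 within each category. ``allowed``
    optionally whitelists category values; unknown values raise with the
    offending entries listed.
    """
    if isinstance(demographics, ResponseTable):
        if demographics.demographics is None:
            raise ValueError("response table carries no demographic columns")
        demographics = demographics.demographics
    if demographics.shape[1] == 0:
        raise ValueError("no demographic columns present")
    if categories is None:
        categories = list(demographics.columns)
    rows = []
    for category in categories:
        if category not in demographics.columns:
            raise ValueError(f"demographic column {category!r} not present")
        col = demographics[category].dropna()
        if allowed and category in allowed:
            offenders = sorted(set(col) - set(allowed[category]))
            if offenders:
                raise ValueError(f"unknown values in {category!r}: {offenders}")
        counts = col.value_counts()
        for value, count in counts.items():
            rows.append(
                {
                    "category": category,
                    "value": value,
                    "percent": round(100.0 * count / len(col), 2),
                }
            )
    return pd.DataFrame(rows)


def pool_scores(score_series: Sequence[pd.Series]) -> pd.DataFrame:
    """Pool per-imputation score vectors: mean and across-imputation SD."""
    if not score_series:
        raise ValueError("nothing to pool")
    stacked = pd.concat(score_series, axis=1)
    return pd.DataFrame(
        {"score": stacked.mean(axis=1), "between_imputation_sd": stacked.std(axis=1, ddof=0)}
    )
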