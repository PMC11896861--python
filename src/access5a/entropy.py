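"""Entropy weight method and hierarchical weight aggregation.

Objective indicator weighting: indicators whose values differ more across
the n evaluation objects carry more information (lower Shannon entropy)
and receive larger weights. The chain is

    min-max normalisation (direction-aware)
    -> column proportions        p_ij = x_ij / sum_i x_ij
    -> entropy                   e_j  = -(1/ln n) sum_i p_ij ln p_ij
    -> redundancy (utility)      d_j  = 1 - e_j
    -> weight                    w_j  = d_j / sum_j d_j

with 0 * ln 0 := 0. Leaf weights are then aggregated bottom-up through
the indicator hierarchy: each parent's weight is the sum of its
children's weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .hierarchy import IndicatorHierarchy, validate_weight_rollup

__all__ = [
    "DataMatrix",
    "EntropyBreakdown",
    "DegenerateColumnError",
    "normalize",
    "entropy_weights",
    "assign_and_rollup",
]


class DegenerateColumnError(ValueError):
    """A constant column cannot be min-max normalised."""


@dataclass
class DataMatrix:
    """n evaluation objects (rows) x m indicators (columns), with per-column
    optimisation directions.

    ``directions`` maps column id -> ``"positive"`` (larger is better) or
    ``"negative"``; unlisted columns default to positive.
    """

    values: pd.DataFrame
    directions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 evaluation objects (rows)")
        if self.values.isna().any().any():
            raise ValueError("data matrix contains missing cells; impute upstream")
        directions = dict(self.directions or {})
        unknown = set(directions) - set(self.values.columns)
        if unknown:
            raise ValueError(f"directions given for unknown columns: {sorted(unknown)}")
        bad = {c: d for c, d in directions.items() if d not in ("positive", "negative")}
        if bad:
            raise ValueError(f"invalid directions: {bad}")
        self.directions = directions

    def direction(self, column: str) -> str:
        return self.directions.get(column, "positive")


@dataclass
class EntropyBreakdown:
    """Per-column intermediates of the entropy weight computation."""

    normalized: pd.DataFrame
    proportions: pd.DataFrame
    entropy: pd.Series
    redundancy: pd.Series
    weights: pd.Series


def _as_matrix(data: DataMatrix | pd.DataFrame) -> DataMatrix:
    return data if isinstance(data, DataMatrix) else DataMatrix(values=data)


def normalize(
    data: DataMatrix | pd.DataFrame,
    degenerate: Literal["error", "zero"] = "error",
) -> pd.DataFrame:
    """Direction-aware min-max normalisation onto [0, 1].

    Positive columns map min -> 0, max -> 1; negative columns reflect
    (max -> 0, min -> 1). A constant column has no range: with
    ``degenerate="error"`` it is rejected (naming the column); with
    ``"zero"`` it is set to all zeros and handled downstream as an
    information-free indicator.
    """
    matrix = _as_matrix(data)
    raw = matrix.values
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for column in raw.columns:
        col = raw[column].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            if degenerate == "error":
                raise DegenerateColumnError(
                    f"column {column!r} is constant ({lo}); cannot min-max normalise"
                )
            out[column] = 0.0
            continue
        if matrix.direction(column) == "positive":
            out[column] = (col - lo) / (hi - lo)
        else:
            out[column] = (hi - col) / (hi - lo)
    return out


def entropy_weights(
    data: DataMatrix | pd.DataFrame,
    prenormalized: bool = False,
    shift: float | None = None,
    degenerate: Literal["zero-weight", "error"] = "zero-weight",
) -> EntropyBreakdown:
    """Entropy weights for every column of a data matrix.

    Parameters
    ----------
    data:
        Raw :class:`DataMatrix` (normalised internally) or, with
        ``prenormalized=True``, a frame already scaled to [0, 1].
    shift:
        Optional epsilon added to all normalised values before computing
        proportions (some practitioners add e.g. 1e-4 to avoid exact
        zeros). Default: no shift; 0*ln 0 is taken as 0.
    degenerate:
        Policy for all-zero (information-free) columns: ``"zero-weight"``
        assigns entropy 1 / weight 0 with a warning, ``"error"`` raises.

    The entropy constant k is 1 / ln(n), which bounds e_j in [0, 1].
    """
    matrix = _as_matrix(data)
    if prenormalized:
        norm = matrix.values.astype(float)
        if (norm.to_numpy() < 0).any() or (norm.to_numpy() > 1).any():
            raise ValueError("prenormalized values must lie in [0, 1]")
    else:
        norm = normalize(matrix, degenerate="error" if degenerate == "error" else "zero")
    if shift is not None:
        if shift <= 0:
            raise ValueError("shift must be positive")
        norm = norm + shift

    n = norm.shape[0]
    k = 1.0 / np.log(n)
    proportions = pd.DataFrame(index=norm.index, columns=norm.columns, dtype=float)
    entropy = pd.Series(index=norm.columns, dtype=float)
    for column in norm.columns:
        col = norm[column].to_numpy(dtype=float)
        total = col.sum()
        if total == 0.0:
            if degenerate == "error":
                raise DegenerateColumnError(
                    f"column {column!r} carries no information (all zeros after normalisation)"
                )
            warnings.warn(
                f"column {column!r} is information-free; assigned entropy 1, weight 0",
                stacklevel=2,
            )
            proportions[column] = 1.0 / n
            entropy[column] = 1.0
            continue
        p = col / total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        entropy[column] = float(-k * terms.sum())
        proportions[column] = p

    redundancy = 1.0 - entropy
    # constant columns hit e_j = 1 only up to float error; snap to zero
    redundancy[redundancy.abs() <= 1e-12] = 0.0
    total_redundancy = redundancy.sum()
    if total_redundancy <= 0:
        raise ValueError(
            "no discriminating information in any column (all entropies are 1); "
            "weights are undefined"
        )
    weights = redundancy / total_redundancy
    return EntropyBreakdown(
        normalized=norm,
        proportions=proportions,
        entropy=entropy,
        redundancy=redundancy,
        weights=weights,
    )


def assign_and_rollup(
    hierarchy: IndicatorHierarchy,
    leaf_weights: Mapping[str, float] | pd.Series,
    tol: float = 1e-6,
) -> IndicatorHierarchy:
    """Assign tertiary weights and aggregate them bottom-up.

    Every level-2 weight becomes the sum of its level-3 children, every
    level-1 weight the sum of its level-2 children. ``leaf_weights`` must
    cover every tertiary indicator and sum to 1 within ``tol``.
    """
    leaf_weights = dict(pd.Series(leaf_weights).items())
    missing = [leaf.id for leaf in hierarchy.leaves if leaf.id not in leaf_weights]
    if missing:
        raise ValueError(f"missing leaf weights for: {missing}")
    total = sum(float(leaf_weights[leaf.id]) for leaf in hierarchy.leaves)
    if abs(total - 1.0) > tol:
        raise ValueError(f"leaf weights sum to {total:.9f}, expected 1 within {tol}")

    weights: dict[str, float] = {leaf.id: float(leaf_weights[leaf.id]) for leaf in hierarchy.leaves}
    for level in (2, 1):
        for node in hierarchy.level_nodes(level):
            weights[node.id] = sum(weights[c.id] for c in hierarchy.children(node.id))
    weighted = hierarchy.with_weights(weights)
    discrepancies = validate_weight_rollup(weighted, tol=tol)
    assert not discrepancies, "bottom-up aggregation must be roll-up consistent"
    return weighted
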