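"""Fuzzy comprehensive evaluation (FCE) of Likert survey responses.

The evaluation set is V = {V1..V5} with V1 = very satisfied down to
V5 = very dissatisfied; grade values (5, 4, 3, 2, 1) attach a score to
each grade. For each tertiary indicator the membership vector is the
relative frequency of each grade among respondents. Membership vectors
are composed up the weighted indicator hierarchy — by default with the
weighted-average operator M(.,+), which preserves all weight information
and makes parent scores exact weighted means of child scores — and each
composite vector is defuzzified by its dot product with the grade values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import DEFAULT_GRADE_VALUES, IndicatorHierarchy

__all__ = [
    "GRADE_LABELS",
    "ResponseTable",
    "EvaluationResult",
    "membership_from_responses",
    "compose",
    "defuzzify",
    "evaluate_hierarchy",
]

#: Ordered grade labels, most to least satisfied.
GRADE_LABELS: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5")

DEMOGRAPHIC_FIELDS: tuple[str, ...] = ("gender", "age", "income", "health", "residence")

Operator = Literal["weighted_average", "max_min"]


@dataclass
class ResponseTable:
    """Survey responses: respondents x tertiary indicators.

    ``scores`` holds grade values on the 1-5 scale where 5 corresponds to
    V1 (very satisfied) and 1 to V5 (very dissatisfied). ``demographics``
    optionally carries categorical respondent attributes on the same
    index. Cells may be missing (NaN) before imputation; analysis entry
    points require a complete table.
    """

    scores: pd.DataFrame
    demographics: pd.DataFrame | None = None
    grade_values: tuple[float, ...] = DEFAULT_GRADE_VALUES

    def __post_init__(self) -> None:
        if self.scores.shape[0] < 1 or self.scores.shape[1] < 1:
            raise ValueError("response table is empty")
        valid = set(self.grade_values)
        observed = set(self.scores.stack().unique())
        bad = {v for v in observed if v not in valid}
        if bad:
            raise ValueError(f"scores outside the declared grade set {sorted(valid)}: {sorted(bad)}")
        if self.demographics is not None and not self.demographics.index.equals(self.scores.index):
            raise ValueError("demographics index must match the scores index")

    @property
    def n_respondents(self) -> int:
        return self.scores.shape[0]

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def missing_fraction(self) -> float:
        return float(self.scores.isna().to_numpy().mean())

    def require_complete(self) -> None:
        if self.scores.isna().any().any():
            cols = list(self.scores.columns[self.scores.isna().any()])
            raise ValueError(f"response table has missing cells in columns {cols}; impute first")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        indicator_ids: Sequence[str],
        grade_values: tuple[float, ...] = DEFAULT_GRADE_VALUES,
    ) -> "ResponseTable":
        """Split a raw survey frame into scores and demographics.

        Indicator columns may contain numeric grade values (1-5, with 5
        = very satisfied) or grade labels ``"V1"``..``"V5"``; labels are
        mapped through ``grade_values`` (V1 -> grade_values[0], ...).
        Non-indicator columns become demographics.
        """
        missing = [c for c in indicator_ids if c not in frame.columns]
        if missing:
            raise ValueError(f"response frame lacks indicator columns: {missing}")
        label_map = {label: grade_values[i] for i, label in enumerate(GRADE_LABELS)}
        scores = frame[list(indicator_ids)].copy()
        for column in scores.columns:
            col = scores[column]
            if col.dtype == object:
                col = col.map(lambda v: label_map.get(v, v) if isinstance(v, str) else v)
            scores[column] = pd.to_numeric(col, errors="raise")
        demo_cols = [c for c in frame.columns if c not in set(indicator_ids)]
        demographics = frame[demo_cols] if demo_cols else None
        return cls(scores=scores, demographics=demographics, grade_values=grade_values)


def membership_from_responses(
    responses: ResponseTable | pd.DataFrame,
    grade_values: Sequence[float] = DEFAULT_GRADE_VALUES,
) -> pd.DataFrame:
    """Grade-membership matrix over tertiary indicators.

    Row r, column Vg = fraction of respondents assigning indicator r to
    grade g. Rows sum to 1.
    """
    if isinstance(responses, ResponseTable):
        responses.require_complete()
        scores = responses.scores
        grade_values = responses.grade_values
    else:
        scores = responses
        if scores.shape[0] < 1:
            raise ValueError("response table is empty")
        if scores.isna().any().any():
            raise ValueError("response table has missing cells; impute first")
    n = scores.shape[0]
    membership = pd.DataFrame(index=scores.columns, columns=list(GRADE_LABELS), dtype=float)
    for label, value in zip(GRADE_LABELS, grade_values):
        membership[label] = (scores == value).sum(axis=0) / n
    return membership


def compose(
    weights: Sequence[float] | pd.Series,
    memberships: pd.DataFrame | np.ndarray,
    operator: Operator = "weighted_average",
) -> np.ndarray:
    """Compose a sibling block's membership rows into one vector.

    Weights are renormalised to sum 1 within the block. The default
    weighted-average operator returns ``sum_r w'_r * R_r``, which
    conserves total membership; the classical max-min operator
    ``max_r min(w'_r, R_rg)`` is available for comparison (its output is
    renormalised to sum 1 so scores stay comparable).
    """
    w = np.asarray(weights, dtype=float)
    rows = np.asarray(memberships, dtype=float)
    if rows.ndim == 1:
        rows = rows.reshape(1, -1)
    if w.ndim != 1 or w.shape[0] != rows.shape[0]:
        raise ValueError(f"{w.shape[0]} weights for {rows.shape[0]} membership rows")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    w = w / total
    if operator == "weighted_average":
        return w @ rows
    if operator == "max_min":
        combined = np.minimum(w[:, None], rows).max(axis=0)
        s = combined.sum()
        if s <= 0:
            raise ValueError("max-min composition produced an all-zero vector")
        return combined / s
    raise ValueError(f"unknown composition operator {operator!r}")


def defuzzify(
    membership: Sequence[float],
    grade_values: Sequence[float] = DEFAULT_GRADE_VALUES,
    tol: float = 0.005,
    renormalize: bool = False,
) -> float:
    """Collapse a membership vector to a score: dot product with grade values.

    The vector must be nonnegative and sum to 1 within ``tol`` (default
    0.005, loose enough to accept externally reported vectors whose
    printed entries sum to e.g. 0.9999). No renormalisation is applied
    unless requested.
    """
    vec = np.asarray(membership, dtype=float)
    grades = np.asarray(grade_values, dtype=float)
    if vec.shape != grades.shape:
        raise ValueError(f"membership has {vec.shape[0]} entries for {grades.shape[0]} grades")
    if (vec < 0).any():
        raise ValueError("membership entries must be nonnegative")
    deviation = abs(float(vec.sum()) - 1.0)
    if deviation > tol:
        raise ValueError(
            f"membership vector sums to {vec.sum():.6f}; deviates from 1 by "
            f"{deviation:.6f} (> tolerance {tol})"
        )
    if renormalize:
        vec = vec / vec.sum()
    return float(vec @ grades)


@dataclass
class EvaluationResult:
    """Composite membership vectors and defuzzified scores for every node.

    ``memberships`` is indexed by node id (plus ``"overall"``) with one
    column per grade; ``scores`` is the matching defuzzified score series.
    """

    memberships: pd.DataFrame
    scores: pd.Series
    hierarchy: IndicatorHierarchy
    operator: Operator = "weighted_average"

    @property
    def overall_score(self) -> float:
        return float(self.scores["overall"])

    def to_table(self) -> pd.DataFrame:
        """Wide per-level score layout: one row per tertiary indicator."""
        rows = []
        for leaf in self.hierarchy.leaves:
            secondary = self.hierarchy.node(leaf.parent_id)
            primary = self.hierarchy.node(secondary.parent_id)
            rows.append(
                {
                    "primary": primary.id,
                    "primary_score": self.scores[primary.id],
                    "secondary": secondary.id,
                    "secondary_score": self.scores[secondary.id],
                    "tertiary": leaf.id,
                    "tertiary_score": self.scores[leaf.id],
                }
            )
        return pd.DataFrame(rows)

    def to_long(self) -> pd.DataFrame:
        """Long-format membership export (node, grade, membership, score)."""
        long = (
            self.memberships.rename_axis("node_id")
            .reset_index()
            .melt(id_vars="node_id", var_name="grade", value_name="membership")
        )
        long["score"] = long["node_id"].map(self.scores)
        return long.sort_values(["node_id", "grade"]).reset_index(drop=True)


def evaluate_hierarchy(
    responses: ResponseTable | pd.DataFrame,
    hierarchy: IndicatorHierarchy,
    operator: Operator = "weighted_average",
) -> EvaluationResult:
    """Full FCE pass: tertiary memberships, weighted composition up the
    tree, defuzzified scores at every node and overall.

    The hierarchy must be fully weighted and the responses must cover
    every tertiary indicator.
    """
    hierarchy.weights()
    scores_frame = responses.scores if isinstance(responses, ResponseTable) else responses
    missing = [leaf.id for leaf in hierarchy.leaves if leaf.id not in scores_frame.columns]
    if missing:
        raise ValueError(f"responses lack tertiary indicator columns: {missing}")

    grade_values = hierarchy.grade_values
    leaf_membership = membership_from_responses(
        scores_frame[hierarchy.leaf_ids], grade_values=grade_values
    )

    vectors: dict[str, np.ndarray] = {
        leaf: leaf_membership.loc[leaf].to_numpy() for leaf in hierarchy.leaf_ids
    }
    for level in (2, 1):
        for node in hierarchy.level_nodes(level):
            children = hierarchy.children(node.id)
            block = np.vstack([vectors[c.id] for c in children])
            w = [c.weight for c in children]
            vectors[node.id] = compose(w, block, operator=operator)
    roots = hierarchy.level_nodes(1)
    vectors["overall"] = compose(
        [r.weight for r in roots], np.vstack([vectors[r.id] for r in roots]), operator=operator
    )

    order = [n.id for n in hierarchy.nodes] + ["overall"]
    memberships = pd.DataFrame(
        [vectors[node_id] for node_id in order], index=order, columns=list(GRADE_LABELS)
    )
    scores = pd.Series(
        {node_id: defuzzify(vectors[node_id], grade_values, tol=1e-6) for node_id in order},
        name="score",
    )
    return EvaluationResult(
        memberships=memberships, scores=scores, hierarchy=hierarchy, operator=operator
    )
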