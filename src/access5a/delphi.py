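"""Delphi expert-consultation statistics.

Covers the quantitative side of a two-round Delphi panel used to build an
indicator system: the expert authority coefficient Cr = (Ca + Cs) / 2,
Kendall's coefficient of concordance W (with the standard tie correction
for heavily tied Likert importance ratings), its asymptotic chi-square
significance test, and mean/CV screening of candidate indicators between
rounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpertProfile",
    "ExpertRatingRound",
    "ConcordanceResult",
    "ScreeningResult",
    "ConsultationReport",
    "authority_coefficient",
    "kendalls_w",
    "screen_indicators",
    "consultation_report",
]


@dataclass(frozen=True)
class ExpertProfile:
    """Self-assessed authority components of one panel expert.

    ``ca`` is the judgment-basis coefficient, ``cs`` the familiarity
    coefficient, both quantified on [0, 1] upstream of this package.
    """

    expert_id: str
    ca: float
    cs: float

    def __post_init__(self) -> None:
        for name, value in (("ca", self.ca), ("cs", self.cs)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"expert {self.expert_id!r}: {name}={value} outside [0, 1]")

    @property
    def cr(self) -> float:
        return authority_coefficient(self.ca, self.cs)


def authority_coefficient(ca: float, cs: float) -> float:
    """Expert authority coefficient Cr = (Ca + Cs) / 2.

    Both arguments must lie in [0, 1]; Cr >= 0.70 is conventionally
    considered acceptable expert authority.
    """
    if not (0.0 <= ca <= 1.0) or not (0.0 <= cs <= 1.0):
        raise ValueError(f"Ca and Cs must lie in [0, 1]; got Ca={ca}, Cs={cs}")
    return (ca + cs) / 2.0


@dataclass
class ExpertRatingRound:
    """Importance ratings from one Delphi round.

    ``ratings`` is an experts x indicators frame of integer importance
    scores on a 1-5 scale (index = expert ids, columns = indicator ids).
    """

    round_number: int
    ratings: pd.DataFrame

    def __post_init__(self) -> None:
        if self.round_number < 1:
            raise ValueError("round_number must be >= 1")
        if self.ratings.empty:
            raise ValueError("ratings matrix is empty")
        values = self.ratings.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("ratings matrix contains missing cells")
        if not np.all(values == np.round(values)):
            raise ValueError("importance scores must be integers")
        if values.min() < 1 or values.max() > 5:
            raise ValueError("importance scores must lie in 1..5")

    @property
    def m(self) -> int:
        return self.ratings.shape[0]

    @property
    def n(self) -> int:
        return self.ratings.shape[1]

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.ratings.columns)


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall's W with its chi-square significance test."""

    W: float
    chi2: float
    df: int
    p: float
    m: int
    n: int
    tie_corrected: bool = True


def kendalls_w(
    rating_round: ExpertRatingRound | pd.DataFrame,
    tie_correction: bool = True,
) -> ConcordanceResult:
    """Kendall's coefficient of concordance over one rating round.

    Each expert's row of importance scores is converted to ranks (average
    ranks for ties). With ``tie_correction`` the denominator subtracts the
    standard tie term ``m * sum_i T_i`` with ``T_i = sum (t^3 - t)`` over
    tie groups in expert i's row; without it, a row with any fully
    constant rating is rejected as an undefined ranking. Significance is
    the asymptotic upper-tail chi-square test with
    ``chi2 = m * (n - 1) * W`` on ``n - 1`` degrees of freedom.
    """
    ratings = rating_round.ratings if isinstance(rating_round, ExpertRatingRound) else rating_round
    m, n = ratings.shape
    if m < 2 or n < 2:
        raise ValueError(f"need at least 2 experts and 2 items, got {m} x {n}")
    values = ratings.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)

    if not tie_correction:
        constant_rows = np.where(values.std(axis=1) == 0)[0]
        if constant_rows.size:
            offenders = [str(ratings.index[i]) for i in constant_rows]
            raise ValueError(
                "constant rating row(s) give an undefined ranking without tie "
                f"correction: experts {offenders}"
            )

    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - m * (n + 1) / 2.0) ** 2).sum())
    denom = m * m * (n**3 - n)
    if tie_correction:
        tie_term = 0.0
        for row in values:
            _, counts = np.unique(row, return_counts=True)
            tie_term += float((counts**3 - counts).sum())
        denom -= m * tie_term
    if denom <= 0:
        raise ValueError("all ratings tied in every row; W is undefined")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return ConcordanceResult(W=w, chi2=chi2, df=df, p=p, m=m, n=n, tie_corrected=tie_correction)


@dataclass
class ScreeningResult:
    """Outcome of mean/CV indicator screening."""

    retained: list[str]
    dropped: list[str]
    stats: pd.DataFrame  # per indicator: mean, sd, cv, retained
    mean_min: float
    cv_max: float


def screen_indicators(
    rating_round: ExpertRatingRound | pd.DataFrame,
    mean_min: float = 3.5,
    cv_max: float = 0.25,
) -> ScreeningResult:
    """Retain indicators with mean importance >= ``mean_min`` and
    coefficient of variation <= ``cv_max``.

    The defaults are common Delphi screening conventions; SD is the
    sample standard deviation (ddof=1).
    """
    if mean_min <= 0 or cv_max <= 0:
        raise ValueError("screening thresholds must be positive")
    ratings = rating_round.ratings if isinstance(rating_round, ExpertRatingRound) else rating_round
    means = ratings.mean(axis=0)
    sds = ratings.std(axis=0, ddof=1)
    cvs = sds / means
    keep = (means >= mean_min) & (cvs <= cv_max)
    table = pd.DataFrame({"mean": means, "sd": sds, "cv": cvs, "retained": keep})
    return ScreeningResult(
        retained=list(table.index[keep]),
        dropped=list(table.index[~keep]),
        stats=table,
        mean_min=mean_min,
        cv_max=cv_max,
    )


# -- consultation summary --------------------------------------------------

_ID_PATTERN = re.compile(r"^[A-Za-z]+(\d*)$")


def _infer_level(indicator_id: str) -> int | None:
    """Level from the id convention 'A' -> 1, 'A1' -> 2, 'A11' -> 3."""
    match = _ID_PATTERN.match(indicator_id)
    if not match:
        return None
    digits = match.group(1)
    if len(digits) > 2:
        return None
    return 1 + len(digits)


@dataclass
class ConsultationReport:
    """Summary tables of a multi-round Delphi consultation."""

    authority: pd.DataFrame  # per round: mean_ca, mean_cs, cr
    concordance: pd.DataFrame  # per round x group: n_items, W, chi2, p

    def to_markdown(self) -> str:
        lines = ["## Expert authority", "", self.authority.round(4).to_markdown(), ""]
        lines += ["## Concordance of expert opinion", "", self.concordance.round(4).to_markdown(), ""]
        return "\n".join(lines)


def consultation_report(
    rounds: Sequence[ExpertRatingRound],
    profiles: Mapping[int, Sequence[ExpertProfile]] | Sequence[Sequence[ExpertProfile]],
    level_of: Callable[[str], int | None] | Mapping[str, int] | None = None,
    tie_correction: bool = True,
) -> ConsultationReport:
    """Authority and concordance summary across consultation rounds.

    For each round the report carries mean Ca, mean Cs and the round Cr,
    plus Kendall's W / chi-square / p overall and per indicator level
    (levels inferred from the id convention ``A`` / ``A1`` / ``A11``
    unless ``level_of`` is supplied).
    """
    if not rounds:
        raise ValueError("need at least one consultation round")
    if isinstance(profiles, Mapping):
        profile_map = dict(profiles)
    else:
        profile_map = {r.round_number: p for r, p in zip(rounds, profiles)}

    if level_of is None:
        resolve = _infer_level
    elif isinstance(level_of, Mapping):
        resolve = lambda i: level_of.get(i)  # noqa: E731
    else:
        resolve = level_of

    authority_rows = []
    for rnd in rounds:
        panel = profile_map.get(rnd.round_number, [])
        if not panel:
            raise ValueError(f"no expert profiles supplied for round {rnd.round_number}")
        mean_ca = float(np.mean([p.ca for p in panel]))
        mean_cs = float(np.mean([p.cs for p in panel]))
        authority_rows.append(
            {
                "round": rnd.round_number,
                "mean_ca": mean_ca,
                "mean_cs": mean_cs,
                "cr": authority_coefficient(mean_ca, mean_cs),
            }
        )

    concordance_rows = []
    for rnd in rounds:
        groups: list[tuple[str, list[str]]] = [("overall", rnd.indicator_ids)]
        by_level: dict[int, list[str]] = {}
        for ind in rnd.indicator_ids:
            lv = resolve(ind)
            if lv is not None:
                by_level.setdefault(lv, []).append(ind)
        for lv in sorted(by_level):
            groups.append((f"level_{lv}", by_level[lv]))
        for group_name, ids in groups:
            if len(ids) < 2:
                continue
            res = kendalls_w(rnd.ratings[ids], tie_correction=tie_correction)
            concordance_rows.append(
                {
                    "round": rnd.round_number,
                    "group": group_name,
                    "n_items": res.n,
                    "W": res.W,
                    "chi2": res.chi2,
                    "p": res.p,
                }
            )

    return ConsultationReport(
        authority=pd.DataFrame(authority_rows).set_index("round"),
        concordance=pd.DataFrame(concordance_rows).set_index(["round", "group"]),
    )
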