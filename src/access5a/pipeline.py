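"""End-to-end evaluation pipeline and file-level I/O.

Ties the stages together the way the methodology is applied in practice:
Delphi consultation summary and screening -> entropy weighting of the
survey data -> bottom-up weight roll-up -> fuzzy comprehensive
evaluation -> tabular reports. Every run writes its intermediates to a
run directory, stamps every CSV with a metadata header (tool version,
config hash, seed) and is reproducible given the same config and seed.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml

from . import __version__
from .delphi import ExpertProfile, ExpertRatingRound, consultation_report, screen_indicators
from .entropy import DataMatrix, assign_and_rollup, entropy_weights
from .fce import ResponseTable, evaluate_hierarchy
from .hierarchy import IndicatorHierarchy, load_hierarchy
from .survey import impute_missing, pool_scores, respondent_summary

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "read_expert_round",
    "read_expert_profiles",
    "read_responses",
    "write_csv_with_header",
    "weights_table",
]

logger = logging.getLogger("access5a")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """Paths and options for one end-to-end run."""

    hierarchy: str
    responses: str
    expert_ratings: list[str] = field(default_factory=list)
    expert_profiles: list[str] = field(default_factory=list)
    mean_min: float = 3.5
    cv_max: float = 0.25
    weights_source: Literal["entropy", "hierarchy"] = "entropy"
    operator: Literal["weighted_average", "max_min"] = "weighted_average"
    m_imputations: int = 5
    seed: int | None = None
    out_dir: str = "access5a_run"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]


# -- file readers ----------------------------------------------------------


def read_expert_round(path, round_number: int = 1) -> ExpertRatingRound:
    """Expert ratings CSV: first column expert_id, one column per indicator."""
    frame = pd.read_csv(path, comment="#").set_index("expert_id")
    return ExpertRatingRound(round_number=round_number, ratings=frame)


def read_expert_profiles(path) -> list[ExpertProfile]:
    """Profiles CSV with columns expert_id, ca, cs."""
    frame = pd.read_csv(path, comment="#")
    frame.columns = [c.lower() for c in frame.columns]
    return [
        ExpertProfile(expert_id=str(row["expert_id"]), ca=float(row["ca"]), cs=float(row["cs"]))
        for _, row in frame.iterrows()
    ]


def read_responses(path, hierarchy: IndicatorHierarchy) -> ResponseTable:
    """Responses CSV: respondent_id, demographics, one column per tertiary id."""
    frame = pd.read_csv(path, comment="#")
    if "respondent_id" in frame.columns:
        frame = frame.set_index("respondent_id")
    return ResponseTable.from_frame(frame, hierarchy.leaf_ids, grade_values=hierarchy.grade_values)


def write_csv_with_header(frame: pd.DataFrame, path, meta: dict, index: bool = False) -> None:
    """Write a CSV prefixed with ``# key=value`` metadata comment lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=index)


def weights_table(hierarchy: IndicatorHierarchy) -> pd.DataFrame:
    """Wide per-level weight layout: one row per tertiary indicator."""
    rows = []
    for leaf in hierarchy.leaves:
        secondary = hierarchy.node(leaf.parent_id)
        primary = hierarchy.node(secondary.parent_id)
        rows.append(
            {
                "primary": primary.id,
                "primary_label": primary.label,
                "primary_weight": round(primary.weight, 4),
                "secondary": secondary.id,
                "secondary_label": secondary.label,
                "secondary_weight": round(secondary.weight, 4),
                "tertiary": leaf.id,
                "tertiary_label": leaf.label,
                "tertiary_weight": round(leaf.weight, 4),
            }
        )
    return pd.DataFrame(rows)


# -- the pipeline ----------------------------------------------------------


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            start = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.3f s", name, time.perf_counter() - start)
            return result

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and return the run directory.

    Stages: load hierarchy -> Delphi summary & screening (if expert data
    given) -> imputation -> entropy weights (per imputed table, averaged)
    -> roll-up -> FCE (per table, scores pooled by averaging) -> reports.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "access5a_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        hierarchy = _stage("load_hierarchy")(_load_hierarchy_checked)(config.hierarchy)

        if config.expert_ratings:
            _stage("delphi")(_delphi_stage)(config, out_dir, meta)

        responses = _stage("read_responses")(_read_responses_checked)(config, hierarchy)
        imputation = _stage("impute")(impute_missing)(
            responses, m_imputations=config.m_imputations, seed=config.seed
        )
        if not imputation.log.empty:
            write_csv_with_header(imputation.log, out_dir / "imputation_log.csv", meta)

        weighted = _stage("weights")(_weights_stage)(config, hierarchy, imputation.tables)
        write_csv_with_header(weights_table(weighted), out_dir / "weights.csv", meta)

        results = [
            _stage("evaluate")(evaluate_hierarchy)(table, weighted, operator=config.operator)
            for table in imputation.tables
        ]
        pooled = pool_scores([r.scores for r in results]).round(4)
        score_table = results[0].to_table().copy()
        for column in ("primary_score", "secondary_score", "tertiary_score"):
            node_col = column.replace("_score", "")
            score_table[column] = score_table[node_col].map(pooled["score"]).round(4)
        write_csv_with_header(score_table, out_dir / "scores.csv", meta)
        write_csv_with_header(
            pooled.rename_axis("node_id").reset_index(), out_dir / "scores_pooled.csv", meta
        )
        write_csv_with_header(results[0].to_long(), out_dir / "memberships_long.csv", meta)

        if responses.demographics is not None and responses.demographics.shape[1] > 0:
            write_csv_with_header(
                respondent_summary(responses), out_dir / "respondent_summary.csv", meta
            )

        (out_dir / "config_used.yaml").write_text(
            yaml.safe_dump({**config.to_dict(), **meta}, sort_keys=False), encoding="utf-8"
        )
        logger.info("run complete; overall score %.4f", pooled.loc["overall", "score"])
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir


def _load_hierarchy_checked(path: str) -> IndicatorHierarchy:
    if not Path(path).exists():
        raise FileNotFoundError(f"hierarchy config not found: {path}")
    return load_hierarchy(path)


def _read_responses_checked(config: PipelineConfig, hierarchy: IndicatorHierarchy) -> ResponseTable:
    if not Path(config.responses).exists():
        raise FileNotFoundError(f"responses file not found: {config.responses}")
    return read_responses(config.responses, hierarchy)


def _delphi_stage(config: PipelineConfig, out_dir: Path, meta: dict) -> None:
    rounds = []
    for i, path in enumerate(config.expert_ratings, start=1):
        if not Path(path).exists():
            raise FileNotFoundError(f"expert ratings file not found: {path}")
        rounds.append(read_expert_round(path, round_number=i))
    profiles = {}
    for i, path in enumerate(config.expert_profiles, start=1):
        profiles[i] = read_expert_profiles(path)
    report = consultation_report(rounds, profiles)
    (out_dir / "delphi_report.md").write_text(report.to_markdown(), encoding="utf-8")
    screening = screen_indicators(rounds[-1], mean_min=config.mean_min, cv_max=config.cv_max)
    write_csv_with_header(
        screening.stats.rename_axis("indicator_id").reset_index(),
        out_dir / "screening.csv",
        meta,
    )


def _weights_stage(
    config: PipelineConfig,
    hierarchy: IndicatorHierarchy,
    tables: Sequence[ResponseTable],
) -> IndicatorHierarchy:
    if config.weights_source == "hierarchy":
        hierarchy.weights()  # must already be fully weighted
        return hierarchy
    directions = {leaf.id: leaf.direction for leaf in hierarchy.leaves}
    per_table = []
    for table in tables:
        matrix = DataMatrix(values=table.scores[hierarchy.leaf_ids], directions=directions)
        per_table.append(entropy_weights(matrix).weights)
    mean_weights = pd.concat(per_table, axis=1).mean(axis=1)
    return assign_and_rollup(hierarchy, mean_weights / mean_weights.sum())
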