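import numpy as np
import pandas as pd
import pytest

from access5a import (
    IndicatorHierarchy,
    IndicatorNode,
    ResponseTable,
    load_xian_hierarchy,
    load_xian_scores,
)


@pytest.fixture(scope="session")
def xian_hierarchy() -> IndicatorHierarchy:
    """Bundled published 5/14/37 indicator system with weights."""
    return load_xian_hierarchy()


@pytest.fixture(scope="session")
def xian_scores() -> pd.Series:
    """Bundled published per-node defuzzified scores (plus 'overall')."""
    return load_xian_scores()


@pytest.fixture
def chain_hierarchy() -> IndicatorHierarchy:
    """Minimal valid tree: one node per level, all weights 1."""
    return IndicatorHierarchy(
        [
            IndicatorNode("A", "root", 1, weight=1.0),
            IndicatorNode("A1", "mid", 2, parent_id="A", weight=1.0),
            IndicatorNode("A11", "leaf", 3, parent_id="A1", weight=1.0),
        ]
    )


@pytest.fixture
def small_hierarchy() -> IndicatorHierarchy:
    """Two primary dimensions, three secondary, four leaves; weighted."""
    return IndicatorHierarchy(
        [
            IndicatorNode("A", "dim A", 1, weight=0.6),
            IndicatorNode("A1", "A one", 2, parent_id="A", weight=0.4),
            IndicatorNode("A11", "leaf A11", 3, parent_id="A1", weight=0.4),
            IndicatorNode("A2", "A two", 2, parent_id="A", weight=0.2),
            IndicatorNode("A21", "leaf A21", 3, parent_id="A2", weight=0.2),
            IndicatorNode("B", "dim B", 1, weight=0.4),
            IndicatorNode("B1", "B one", 2, parent_id="B", weight=0.4),
            IndicatorNode("B11", "leaf B11", 3, parent_id="B1", weight=0.25),
            IndicatorNode("B12", "leaf B12", 3, parent_id="B1", weight=0.15),
        ]
    )


@pytest.fixture
def small_responses(small_hierarchy) -> ResponseTable:
    rng = np.random.default_rng(42)
    leaf_ids = small_hierarchy.leaf_ids
    scores = pd.DataFrame(
        rng.integers(1, 6, size=(30, len(leaf_ids))).astype(float),
        columns=leaf_ids,
        index=pd.RangeIndex(1, 31, name="respondent_id"),
    )
    return ResponseTable(scores=scores)
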