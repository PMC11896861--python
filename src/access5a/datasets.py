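"""Bundled reference data: the published indicator system and scores.

The package ships three small fixtures from the Xi'an urban elderly-care
accessibility study:

* the 5/14/37 indicator hierarchy with its published entropy weights,
* the published defuzzified scores for every node plus the overall index,
* a synthetic-survey population profile whose latent means are those scores.

The published weights and scores are *fixtures*, not recomputable outputs:
the underlying raw survey was never deposited. They are used for
internal-consistency checks (weight roll-up, score aggregation) and as
realistic defaults for the synthetic generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .hierarchy import IndicatorHierarchy, load_hierarchy

__all__ = [
    "load_xian_hierarchy",
    "load_xian_scores",
    "load_xian_profile_dict",
]


def _data(name: str):
    return resources.files("access5a.data").joinpath(name)


def load_xian_hierarchy() -> IndicatorHierarchy:
    """The published 5/14/37 indicator hierarchy with entropy weights."""
    with _data("xian_table5.yaml").open("r", encoding="utf-8") as fh:
        return load_hierarchy(fh)


def load_xian_scores() -> pd.Series:
    """Published defuzzified scores per node id (plus ``"overall"``)."""
    with _data("xian_table6_scores.csv").open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    return frame.set_index("node_id")["score"]


def load_xian_profile_dict() -> dict:
    """Raw mapping for the bundled synthetic-survey population profile."""
    with _data("xian_like_profile.yaml").open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
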