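"""Three-level indicator hierarchies for composite accessibility evaluation.

An evaluation framework of this kind organises its criteria as a tree:
a handful of primary dimensions (e.g. availability, affordability), each
split into secondary indicators, each of which is measured through
tertiary (leaf) indicators that map onto individual survey items.
Weights live on every node; once assigned, the weight of any parent must
equal the sum of its children's weights, and the primary weights sum to 1.

The module provides the :class:`IndicatorHierarchy` container, a YAML/JSON
config loader with explicit structural validation, and a roll-up
consistency checker.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "IndicatorNode",
    "IndicatorHierarchy",
    "HierarchyError",
    "RollupDiscrepancy",
    "load_hierarchy",
    "dump_hierarchy",
    "validate_weight_rollup",
]

#: Grade values attached to the ordered evaluation set V1..V5
#: (V1 = very satisfied -> 5, V5 = very dissatisfied -> 1).
DEFAULT_GRADE_VALUES: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0, 1.0)

_DIRECTIONS = ("positive", "negative")


class HierarchyError(ValueError):
    """Raised for structurally invalid hierarchy configurations."""


@dataclass
class IndicatorNode:
    """One node of the indicator tree.

    Parameters
    ----------
    id:
        Short code, e.g. ``"A"`` (primary), ``"C2"`` (secondary),
        ``"E23"`` (tertiary). Unique within a hierarchy.
    label:
        Human-readable indicator name.
    level:
        1, 2 or 3; level-3 nodes are leaves.
    parent_id:
        Code of the parent node (``None`` for level-1 nodes).
    direction:
        ``"positive"`` if larger raw values are better, ``"negative"``
        otherwise; consumed by entropy normalisation.
    weight:
        Fraction of total weight carried by this node, or ``None`` if
        weights have not been assigned yet.
    """

    id: str
    label: str
    level: int
    parent_id: str | None = None
    direction: str = "positive"
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise HierarchyError(f"node {self.id!r}: level must be 1, 2 or 3, got {self.level}")
        if self.direction not in _DIRECTIONS:
            raise HierarchyError(
                f"node {self.id!r}: direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )
        if self.weight is not None and not (0.0 <= self.weight <= 1.0):
            raise HierarchyError(f"node {self.id!r}: weight {self.weight} outside [0, 1]")


@dataclass
class IndicatorHierarchy:
    """An ordered collection of :class:`IndicatorNode` plus grade values."""

    nodes: list[IndicatorNode]
    grade_values: tuple[float, ...] = DEFAULT_GRADE_VALUES

    _index: dict[str, IndicatorNode] = field(init=False, repr=False, compare=False)
    _children: dict[str, list[str]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._reindex()
        self._validate_structure()

    def _reindex(self) -> None:
        self._index = {}
        self._children = {}
        for node in self.nodes:
            if node.id in self._index:
                raise HierarchyError(f"duplicate indicator id {node.id!r}")
            self._index[node.id] = node
        for node in self.nodes:
            if node.parent_id is not None:
                self._children.setdefault(node.parent_id, []).append(node.id)

    def _validate_structure(self) -> None:
        for node in self.nodes:
            if node.level == 1:
                if node.parent_id is not None:
                    raise HierarchyError(f"level-1 node {node.id!r} must not have a parent")
                continue
            if node.parent_id is None:
                raise HierarchyError(f"level-{node.level} node {node.id!r} has no parent")
            parent = self._index.get(node.parent_id)
            if parent is None:
                raise HierarchyError(
                    f"node {node.id!r} references missing parent {node.parent_id!r}"
                )
            if parent.level != node.level - 1:
                raise HierarchyError(
                    f"node {node.id!r} (level {node.level}) has parent {parent.id!r} "
                    f"at level {parent.level}; parents must be exactly one level up"
                )
        for node in self.level_nodes(3):
            if self._children.get(node.id):
                raise HierarchyError(f"level-3 node {node.id!r} must be a leaf")

    # -- accessors ---------------------------------------------------------

    def node(self, node_id: str) -> IndicatorNode:
        try:
            return self._index[node_id]
        except KeyError:
            raise HierarchyError(f"unknown indicator id {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def children(self, node_id: str) -> list[IndicatorNode]:
        return [self._index[c] for c in self._children.get(node_id, [])]

    def level_nodes(self, level: int) -> list[IndicatorNode]:
        return [n for n in self.nodes if n.level == level]

    @property
    def leaves(self) -> list[IndicatorNode]:
        return self.level_nodes(3)

    @property
    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves]

    def leaf_descendants(self, node_id: str) -> list[IndicatorNode]:
        node = self.node(node_id)
        if node.level == 3:
            return [node]
        out: list[IndicatorNode] = []
        for child in self.children(node_id):
            out.extend(self.leaf_descendants(child.id))
        return out

    def weights(self) -> dict[str, float]:
        """Mapping id -> weight; raises if any weight is unset."""
        out = {}
        for node in self.nodes:
            if node.weight is None:
                raise HierarchyError(f"weight unset for node {node.id!r}")
            out[node.id] = node.weight
        return out

    def with_weights(self, weights: Mapping[str, float]) -> "IndicatorHierarchy":
        """Return a copy with node weights replaced from ``weights``."""
        new_nodes = [
            replace(n, weight=float(weights[n.id])) if n.id in weights else replace(n)
            for n in self.nodes
        ]
        return IndicatorHierarchy(new_nodes, grade_values=self.grade_values)

    def counts(self) -> tuple[int, int, int]:
        return tuple(len(self.level_nodes(lv)) for lv in (1, 2, 3))  # type: ignore[return-value]


@dataclass
class RollupDiscrepancy:
    """A parent node whose weight disagrees with its descendants."""

    parent_id: str
    declared: float
    child_sum: float
    leaf_sum: float
    tol: float

    @property
    def child_delta(self) -> float:
        return self.child_sum - self.declared

    @property
    def leaf_delta(self) -> float:
        return self.leaf_sum - self.declared


def validate_weight_rollup(
    hierarchy: IndicatorHierarchy, tol: float = 1e-4
) -> list[RollupDiscrepancy]:
    """Check additive weight consistency over the whole tree.

    Every parent is compared both against the sum of its direct children's
    weights and against the sum over its leaf descendants; it is reported
    when either deviates by more than ``tol``. An empty report means the
    hierarchy is roll-up consistent.
    """
    hierarchy.weights()  # raises naming the node if any weight is unset
    report: list[RollupDiscrepancy] = []
    for node in hierarchy.nodes:
        children = hierarchy.children(node.id)
        if not children:
            continue
        child_sum = sum(c.weight for c in children)  # type: ignore[misc]
        leaf_sum = sum(l.weight for l in hierarchy.leaf_descendants(node.id))  # type: ignore[misc]
        declared = node.weight  # type: ignore[assignment]
        if abs(child_sum - declared) > tol or abs(leaf_sum - declared) > tol:
            report.append(RollupDiscrepancy(node.id, declared, child_sum, leaf_sum, tol))
    return report


# -- config I/O ------------------------------------------------------------

_SUPPORTED_VERSIONS = (1,)


def load_hierarchy(source) -> IndicatorHierarchy:
    """Load a hierarchy from a YAML/JSON config.

    ``source`` may be a path, an open text stream, a YAML string, or an
    already-parsed mapping. The config carries a ``version`` field, an
    optional ``grade_values`` list and a ``nodes`` list; each node entry
    has ``id``, ``label``, ``level``, optional ``parent``, ``direction``
    and ``weight``. Structural errors are reported with the offending id.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text(encoding="utf-8")
        elif isinstance(source, io.IOBase) or hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise HierarchyError("hierarchy config must be a mapping")
    version = doc.get("version")
    if version not in _SUPPORTED_VERSIONS:
        raise HierarchyError(f"unsupported config version {version!r}; expected one of {_SUPPORTED_VERSIONS}")
    raw_nodes = doc.get("nodes")
    if not raw_nodes:
        raise HierarchyError("hierarchy config has no nodes")
    nodes = []
    for entry in raw_nodes:
        missing = {"id", "label", "level"} - set(entry)
        if missing:
            raise HierarchyError(f"node entry {entry.get('id')!r} missing fields {sorted(missing)}")
        weight = entry.get("weight")
        nodes.append(
            IndicatorNode(
                id=str(entry["id"]),
                label=str(entry["label"]),
                level=int(entry["level"]),
                parent_id=entry.get("parent"),
                direction=entry.get("direction", "positive"),
                weight=None if weight is None else float(weight),
            )
        )
    grade_values = tuple(float(g) for g in doc.get("grade_values", DEFAULT_GRADE_VALUES))
    return IndicatorHierarchy(nodes, grade_values=grade_values)


def dump_hierarchy(hierarchy: IndicatorHierarchy, path=None) -> str:
    """Serialise to the same YAML config format accepted by :func:`load_hierarchy`."""
    doc = {
        "version": 1,
        "grade_values": list(hierarchy.grade_values),
        "nodes": [
            {
                "id": n.id,
                "label": n.label,
                "level": n.level,
                **({"parent": n.parent_id} if n.parent_id is not None else {}),
                **({"direction": n.direction} if n.direction != "positive" else {}),
                **({"weight": n.weight} if n.weight is not None else {}),
            }
            for n in hierarchy.nodes
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
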