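"""Disease taxonomy: a rooted tree of disease classes with per-level label algebra.

The taxonomy is the single source of truth for class ordering.  Every other
component (synthetic data, model heads, evaluation reports) indexes classes by
``class_order[level]`` so that a label vector, a model output and a report
column always mean the same class.

Levels: the root sits at level 0, coarse disease groups at level 1, their
subclasses at level 2.  Deeper levels may be stored (e.g. individual disease
subtypes as level-3 leaves) but the classifier builder only consumes levels
1..max_level of the taxonomy it is given.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DiseaseNode",
    "DiseaseTaxonomy",
    "MultiLevelLabel",
    "TaxonomyError",
    "LabelError",
    "load_taxonomy",
    "save_taxonomy",
    "bundled_taxonomy",
    "ancestors",
    "expand_labels",
    "check_consistency",
]


class TaxonomyError(ValueError):
    """Structural violation of the taxonomy tree invariants."""


class LabelError(ValueError):
    """Invalid label set for a given taxonomy."""


@dataclass(frozen=True)
class DiseaseNode:
    """One class node of the disease tree."""

    id: str
    display_name: str
    level: int
    parent_id: str | None = None


@dataclass
class DiseaseTaxonomy:
    """Rooted tree of :class:`DiseaseNode` with a canonical class order per level.

    Parameters
    ----------
    modality : str
        Image domain tag.  The shipped clinical fixtures use ``"anterior"``
        (ocular surface, slit-lamp) and ``"retinal"`` (fundus photographs);
        each modality is modelled independently.
    nodes : mapping of id -> DiseaseNode
    class_order : mapping level -> ordered list of node ids
        Stable across save/load; model output positions follow it.
    """

    modality: str
    nodes: dict[str, DiseaseNode]
    class_order: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if not self.modality or not isinstance(self.modality, str):
            raise TaxonomyError("modality must be a non-empty string")
        roots = [n for n in self.nodes.values() if n.level == 0]
        if len(roots) != 1:
            raise TaxonomyError(
                f"taxonomy must have exactly one level-0 root, found {len(roots)}"
            )
        root = roots[0]
        if root.parent_id is not None:
            raise TaxonomyError(f"root node {root.id!r} must not have a parent")
        for node in self.nodes.values():
            if node.level < 0:
                raise TaxonomyError(f"node {node.id!r} has negative level")
            if node.level == 0:
                continue
            if node.parent_id is None:
                raise TaxonomyError(f"non-root node {node.id!r} has no parent")
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise TaxonomyError(
                    f"node {node.id!r} cites nonexistent parent {node.parent_id!r}"
                )
            if parent.level != node.level - 1:
                raise TaxonomyError(
                    f"node {node.id!r} (level {node.level}) has parent "
                    f"{parent.id!r} at level {parent.level}; expected level "
                    f"{node.level - 1}"
                )
        # connectivity: walking parents from any node must reach the root
        for node in self.nodes.values():
            seen: set[str] = set()
            cur = node
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise TaxonomyError(f"cycle detected at node {cur.id!r}")
                seen.add(cur.id)
                cur = self.nodes[cur.parent_id]
            if cur.id != root.id:
                raise TaxonomyError(f"node {node.id!r} is not connected to the root")
        # class order: default = insertion order of nodes at each level
        levels = sorted({n.level for n in self.nodes.values() if n.level >= 1})
        for lvl in levels:
            ids = [n.id for n in self.nodes.values() if n.level == lvl]
            if lvl not in self.class_order:
                self.class_order[lvl] = ids
            elif sorted(self.class_order[lvl]) != sorted(ids):
                raise TaxonomyError(
                    f"class_order[{lvl}] is not a permutation of the level-{lvl} ids"
                )

    # -- basic accessors --------------------------------------------------
    @property
    def root(self) -> DiseaseNode:
        return next(n for n in self.nodes.values() if n.level == 0)

    @property
    def max_level(self) -> int:
        return max(n.level for n in self.nodes.values())

    def n_classes(self, level: int) -> int:
        return len(self.class_order[level])

    def index_of(self, node_id: str) -> tuple[int, int]:
        """Return ``(level, position in class_order[level])`` of a node."""
        node = self.node(node_id)
        return node.level, self.class_order[node.level].index(node_id)

    def node(self, node_id: str) -> DiseaseNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown taxonomy node id {node_id!r}") from None

    def content_hash(self) -> str:
        """Stable hash of the node set and class order (checkpoint guard)."""
        payload = json.dumps(_to_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class MultiLevelLabel:
    """Hierarchy-consistent multi-hot label vectors, one per taxonomy level.

    ``vectors[level]`` is a uint8 array aligned with
    ``taxonomy.class_order[level]``.  A set bit at level *l* implies the bit of
    its level-(l-1) ancestor is set.
    """

    vectors: dict[int, np.ndarray]

    def vec(self, level: int) -> np.ndarray:
        return self.vectors[level]

    def positive_ids(self, taxonomy: DiseaseTaxonomy, level: int) -> list[str]:
        order = taxonomy.class_order[level]
        return [order[i] for i in np.flatnonzero(self.vectors[level])]

    def validate(self, taxonomy: DiseaseTaxonomy) -> None:
        finest = max(self.vectors)
        if int(self.vectors[finest].sum()) < 1:
            raise LabelError("no positive label at the finest annotated level")
        for lvl, v in self.vectors.items():
            if v.shape != (taxonomy.n_classes(lvl),):
                raise LabelError(
                    f"level-{lvl} vector length {v.shape} does not match taxonomy"
                )
            if not np.isin(v, (0, 1)).all():
                raise LabelError("label vectors must be binary")
            if lvl == 1:
                continue
            order = taxonomy.class_order[lvl]
            parent_order = taxonomy.class_order[lvl - 1]
            for i in np.flatnonzero(v):
                parent = taxonomy.node(order[i]).parent_id
                if not self.vectors[lvl - 1][parent_order.index(parent)]:
                    raise LabelError(
                        f"label {order[i]!r} set but its ancestor {parent!r} is not"
                    )


# ---------------------------------------------------------------------------
# serialization

def _to_jsonable(tax: DiseaseTaxonomy) -> dict:
    return {
        "modality": tax.modality,
        "nodes": [
            {
                "id": n.id,
                "name": n.display_name,
                "level": n.level,
                "parent": n.parent_id,
            }
            for n in tax.nodes.values()
        ],
        "class_order": {str(k): v for k, v in tax.class_order.items()},
    }


def load_taxonomy(path: str | Path) -> DiseaseTaxonomy:
    """Load and validate a taxonomy from its JSON file.

    The schema is a flat node list (``id``, ``name``, ``level``, ``parent``)
    plus ``modality`` and an explicit ``class_order`` mapping.  Any violation
    of the tree invariants raises :class:`TaxonomyError`.
    """
    with open(path) as fh:
        raw = json.load(fh)
    return _from_jsonable(raw)


def _from_jsonable(raw: Mapping) -> DiseaseTaxonomy:
    nodes: dict[str, DiseaseNode] = {}
    for rec in raw["nodes"]:
        nid = rec["id"]
        if nid in nodes:
            raise TaxonomyError(f"duplicate node id {nid!r}")
        nodes[nid] = DiseaseNode(
            id=nid,
            display_name=rec.get("name", nid),
            level=int(rec["level"]),
            parent_id=rec.get("parent"),
        )
    class_order = {int(k): list(v) for k, v in raw.get("class_order", {}).items()}
    return DiseaseTaxonomy(modality=raw["modality"], nodes=nodes, class_order=class_order)


def save_taxonomy(tax: DiseaseTaxonomy, path: str | Path) -> None:
    """Write a taxonomy as JSON with its class order serialized explicitly."""
    with open(path, "w") as fh:
        json.dump(_to_jsonable(tax), fh, indent=2)
        fh.write("\n")


def bundled_taxonomy(name: str) -> DiseaseTaxonomy:
    """Load one of the taxonomies shipped with the package.

    ``"anterior"`` — 4 level-1 / 9 level-2 ocular-surface classes;
    ``"retinal"`` — 3 level-1 / 8 level-2 fundus classes;
    ``"desk"`` — small 2 level-1 / 4 level-2 fixture used by the synthetic
    end-to-end examples and tests.
    """
    ref = resources.files("ocutax.data").joinpath(f"{name}_taxonomy.json")
    with ref.open() as fh:
        return _from_jsonable(json.load(fh))


# ---------------------------------------------------------------------------
# label algebra

def ancestors(taxonomy: DiseaseTaxonomy, node_id: str) -> list[str]:
    """Ancestor chain of a node, ordered level 1 .. level-1 of the node.

    Level-1 nodes (and the root) have no ancestors below the root, so the
    list is empty for them.
    """
    node = taxonomy.node(node_id)
    chain: list[str] = []
    while node.parent_id is not None:
        node = taxonomy.node(node.parent_id)
        if node.level >= 1:
            chain.append(node.id)
    chain.reverse()
    return chain


def expand_labels(
    taxonomy: DiseaseTaxonomy, finest_labels: Iterable[str], level: int | None = None
) -> MultiLevelLabel:
    """Upward-close a set of finest-level labels into per-level multi-hot vectors.

    Given level-2 ids, the level-2 bits are set exactly for those ids and the
    level-1 bits exactly for their ancestors, producing a hierarchy-consistent
    :class:`MultiLevelLabel`.
    """
    ids = list(finest_labels)
    if not ids:
        raise LabelError("finest label set must be non-empty")
    if level is None:
        # classifiers consume levels 1-2; deeper stored leaves are ignored
        level = 2 if 2 in taxonomy.class_order else taxonomy.max_level
    vectors = {
        lvl: np.zeros(taxonomy.n_classes(lvl), dtype=np.uint8)
        for lvl in range(1, level + 1)
    }
    for nid in ids:
        node = taxonomy.node(nid)
        if node.level != level:
            raise LabelError(
                f"label {nid!r} is at level {node.level}, expected level {level}"
            )
        vectors[level][taxonomy.class_order[level].index(nid)] = 1
        for anc in ancestors(taxonomy, nid):
            lvl = taxonomy.node(anc).level
            if lvl in vectors:
                vectors[lvl][taxonomy.class_order[lvl].index(anc)] = 1
    label = MultiLevelLabel(vectors)
    label.validate(taxonomy)
    return label


def check_consistency(
    taxonomy: DiseaseTaxonomy,
    scores: Mapping[int, Sequence[float]],
    threshold: float,
) -> list[tuple[str, str]]:
    """Report hierarchy violations in per-level score vectors.

    A violation is a level-l class called positive (score strictly above
    ``threshold``) while its level-(l-1) ancestor is not.  The model does not
    hard-enforce consistency at inference time, so violations are reported
    rather than corrected.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    arrays = {}
    for lvl, vec in scores.items():
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (taxonomy.n_classes(lvl),):
            raise ValueError(
                f"level-{lvl} score vector has length {arr.shape[0]}, "
                f"expected {taxonomy.n_classes(lvl)}"
            )
        arrays[lvl] = arr
    violations: list[tuple[str, str]] = []
    for lvl in sorted(arrays):
        if lvl == 1 or (lvl - 1) not in arrays:
            continue
        order = taxonomy.class_order[lvl]
        parent_order = taxonomy.class_order[lvl - 1]
        for i, nid in enumerate(order):
            if arrays[lvl][i] > threshold:
                parent = taxonomy.node(nid).parent_id
                if arrays[lvl - 1][parent_order.index(parent)] <= threshold:
                    violations.append((nid, parent))
    return violations
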