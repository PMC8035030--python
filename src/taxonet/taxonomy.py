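"""Multi-rank label hierarchies for taxonomic image classification.

A taxonomy here is a tree of named categories organised in ordered ranks
(e.g. Kingdom -> Phylum -> ... -> Species for the iNaturalist hierarchy).
Every image carries one label per rank, and those labels must trace a
single root-to-leaf path.  Category ids are dense 0-based integers per
level, assigned by lexicographic display-name order, so a taxonomy built
from the same records is always identical regardless of record order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TaxonomyError",
    "LabelInconsistencyError",
    "TaxonomyTree",
    "build_taxonomy",
    "ancestor_path",
    "is_consistent_prediction",
    "taxonomy_to_json",
    "taxonomy_from_json",
]


class TaxonomyError(ValueError):
    """Structural problem with a taxonomy or a rank-label vector."""


class LabelInconsistencyError(TaxonomyError):
    """A category name appears under two distinct parents (not a tree)."""


@dataclass(frozen=True)
class TaxonomyTree:
    """The rank hierarchy: named levels, nodes, parent links.

    Attributes
    ----------
    level_names:
        Ordered rank names, coarsest first.
    names:
        ``names[i][c]`` is the display name of category ``c`` at level
        ``i``; ids are dense ``0..level_sizes[i]-1`` in lexicographic
        name order.
    parent:
        ``parent[i][c]`` is the id at level ``i-1`` of the parent of
        category ``c`` at level ``i`` (``i >= 1``); ``parent[0]`` is empty.
    """

    level_names: tuple[str, ...]
    names: tuple[tuple[str, ...], ...]
    parent: tuple[tuple[int, ...], ...]
    _children: tuple[dict[int, tuple[int, ...]], ...] = field(
        init=False, repr=False, compare=False, default=()
    )

    def __post_init__(self) -> None:
        if len(self.level_names) != len(self.names):
            raise TaxonomyError("level_names and names disagree on level count")
        if len(self.parent) != len(self.names):
            raise TaxonomyError("parent and names disagree on level count")
        if self.parent and self.parent[0]:
            raise TaxonomyError("root level must have no parents")
        for i in range(1, self.n_levels):
            if len(self.parent[i]) != len(self.names[i]):
                raise TaxonomyError(f"level {i}: parent links missing for some nodes")
            for c, p in enumerate(self.parent[i]):
                if not 0 <= p < len(self.names[i - 1]):
                    raise TaxonomyError(
                        f"level {i} node {c}: parent id {p} out of range"
                    )
        # child index, built once
        children: list[dict[int, tuple[int, ...]]] = []
        for i in range(self.n_levels - 1):
            by_parent: dict[int, list[int]] = {}
            for c, p in enumerate(self.parent[i + 1]):
                by_parent.setdefault(p, []).append(c)
            children.append({p: tuple(cs) for p, cs in by_parent.items()})
        children.append({})
        object.__setattr__(self, "_children", tuple(children))

    @property
    def n_levels(self) -> int:
        return len(self.level_names)

    @property
    def level_sizes(self) -> list[int]:
        return [len(n) for n in self.names]

    @property
    def n_leaves(self) -> int:
        return len(self.names[-1])

    def name_of(self, level: int, category_id: int) -> str:
        return self.names[level][category_id]

    def id_of(self, level: int, name: str) -> int:
        try:
            return self.names[level].index(name)
        except ValueError:
            raise TaxonomyError(f"unknown category {name!r} at level {level}") from None

    def children_of(self, level: int, category_id: int) -> tuple[int, ...]:
        """Ids at ``level+1`` whose parent is ``category_id``."""
        if category_id not in range(len(self.names[level])):
            raise TaxonomyError(f"unknown category id {category_id} at level {level}")
        return self._children[level].get(category_id, ())

    def leaves_under(self, level: int, category_id: int) -> list[int]:
        """All finest-level ids descending from a node (the node's clade)."""
        ids = [category_id]
        for lvl in range(level, self.n_levels - 1):
            ids = [c for i in ids for c in self.children_of(lvl, i)]
        return ids


def build_taxonomy(
    records: Iterable[Sequence[str]], level_names: Sequence[str]
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from per-sample rank-label tuples.

    Each record is one root-to-leaf path of display names (coarsest
    first).  Ids are assigned densely per level in lexicographic name
    order, so the result is invariant under record permutation and
    duplication.

    Raises
    ------
    LabelInconsistencyError
        If some name appears under two distinct parents across records.
    TaxonomyError
        If a record's length disagrees with ``level_names``.
    """
    level_names = tuple(level_names)
    n_levels = len(level_names)
    seen: list[set[str]] = [set() for _ in range(n_levels)]
    parent_name: list[dict[str, str]] = [dict() for _ in range(n_levels)]
    n_records = 0
    for rec in records:
        n_records += 1
        if len(rec) != n_levels:
            raise TaxonomyError(
                f"record {tuple(rec)!r} has {len(rec)} labels, expected {n_levels}"
            )
        for i, name in enumerate(rec):
            name = str(name)
            seen[i].add(name)
            if i > 0:
                prev = str(rec[i - 1])
                known = parent_name[i].setdefault(name, prev)
                if known != prev:
                    raise LabelInconsistencyError(
                        f"category {name!r} at level {level_names[i]} appears "
                        f"under two parents: {known!r} and {prev!r}"
                    )
    if n_records == 0:
        raise TaxonomyError("no records provided")
    names = tuple(tuple(sorted(s)) for s in seen)
    ids = [{n: j for j, n in enumerate(lvl)} for lvl in names]
    parent: list[tuple[int, ...]] = [()]
    for i in range(1, n_levels):
        parent.append(
            tuple(ids[i - 1][parent_name[i][n]] for n in names[i])
        )
    return TaxonomyTree(level_names=level_names, names=names, parent=tuple(parent))


def ancestor_path(tree: TaxonomyTree, leaf_id: int) -> list[int]:
    """The unique root-to-leaf label vector ending at ``leaf_id``."""
    if not 0 <= leaf_id < tree.n_leaves:
        raise TaxonomyError(f"unknown leaf id {leaf_id}")
    path = [leaf_id]
    for level in range(tree.n_levels - 1, 0, -1):
        path.append(tree.parent[level][path[-1]])
    path.reverse()
    return path


def is_consistent_prediction(tree: TaxonomyTree, labels: Sequence[int]) -> bool:
    """True iff the per-level labels form a valid root-to-leaf path.

    The multilevel classifier's heads are independent, so its argmax
    decisions need not agree across ranks; this diagnostic quantifies
    that cross-level agreement.
    """
    if len(labels) != tree.n_levels:
        return False
    for i, c in enumerate(labels):
        if not 0 <= c < len(tree.names[i]):
            return False
    for i in range(1, tree.n_levels):
        if tree.parent[i][labels[i]] != labels[i - 1]:
            return False
    return True


def taxonomy_to_json(tree: TaxonomyTree) -> str:
    """Serialize to the on-disk JSON document."""
    nodes = []
    for level in range(tree.n_levels):
        for cid, name in enumerate(tree.names[level]):
            nodes.append(
                {
                    "level": level,
                    "id": cid,
                    "name": name,
                    "parent_id": tree.parent[level][cid] if level > 0 else None,
                }
            )
    return json.dumps({"level_names": list(tree.level_names), "nodes": nodes}, indent=1)


def taxonomy_from_json(doc: str) -> TaxonomyTree:
    data = json.loads(doc)
    level_names = tuple(data["level_names"])
    n_levels = len(level_names)
    names: list[dict[int, str]] = [dict() for _ in range(n_levels)]
    parents: list[dict[int, int]] = [dict() for _ in range(n_levels)]
    for node in data["nodes"]:
        lvl, cid = node["level"], node["id"]
        names[lvl][cid] = node["name"]
        if lvl > 0:
            parents[lvl][cid] = node["parent_id"]
    name_tuples = tuple(
        tuple(names[i][c] for c in range(len(names[i]))) for i in range(n_levels)
    )
    parent_tuples: list[tuple[int, ...]] = [()]
    for i in range(1, n_levels):
        parent_tuples.append(tuple(parents[i][c] for c in range(len(names[i]))))
    return TaxonomyTree(
        level_names=level_names, names=name_tuples, parent=tuple(parent_tuples)
    )
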