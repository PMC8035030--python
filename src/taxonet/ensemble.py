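"""Combining fitted multilevel classifiers: accuracy-weighted boosting,
a learned stacking meta-layer, and a coarse-rank-routed cascade.

* Boosting: each member's per-level probability vector is multiplied by
  that member's measured accuracy and the weighted vectors are summed;
  the highest combined score per level is the ensemble decision.
  Weights default to per-level accuracies measured on a held-out
  carve-out of the training split.
* Stacking: a single fully connected layer (one softmax group per
  rank) is trained on the concatenated member outputs (log-probability
  features, so an identity-initialised meta-layer reproduces a single
  member exactly).
* Cascade: a router predicts one coarse rank (e.g. Phylum); the sample
  is forwarded to the specialist trained only on that category's
  subtree, which predicts all finer ranks in a reindexed label space;
  ranks coarser than the routing rank follow from the taxonomy.

Argmax ties break toward the lowest category id everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .dataio import DatasetManifest, SampleRecord
from .model import (
    Adam,
    HeadLayout,
    LinearSoftmaxHeads,
    MultilevelClassifier,
    TinyConvBackbone,
    TrainConfig,
    train,
)
from .taxonomy import TaxonomyTree

__all__ = [
    "MemberModel",
    "measure_member_weights",
    "holdout_split",
    "boost_combine",
    "boost_combine_arrays",
    "StackModel",
    "fit_stacking",
    "stack_combine",
    "CascadeSpec",
    "plan_cascade",
    "build_cascade",
    "cascade_predict",
]


@runtime_checkable
class MemberModel(Protocol):
    """Anything usable as an ensemble member."""

    def predict_arrays(self, images: np.ndarray) -> list[np.ndarray]:
        """Per-level (N, C) probability arrays."""
        ...


# ---------------------------------------------------------------------------
# Boosting
# ---------------------------------------------------------------------------

def holdout_split(
    manifest: DatasetManifest, fraction: float = 0.1, seed: int = 0
) -> tuple[DatasetManifest, list[SampleRecord]]:
    """Carve a stratified (by finest class) holdout out of the train
    split, for measuring ensemble weights without touching test data.

    Returns (reduced manifest, holdout records); at least one record
    per class is held out where a class has more than one record.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    by_class: dict[int, list[int]] = {}
    for i, rec in enumerate(manifest.records):
        if rec.split == "train":
            by_class.setdefault(rec.labels[-1], []).append(i)
    held: set[int] = set()
    for cls in sorted(by_class):
        idx = by_class[cls]
        if len(idx) < 2:
            continue
        n_hold = max(1, int(round(fraction * len(idx))))
        chosen = rng.choice(len(idx), size=n_hold, replace=False)
        held.update(idx[c] for c in chosen)
    kept = [r for i, r in enumerate(manifest.records) if i not in held]
    holdout = [manifest.records[i] for i in sorted(held)]
    return (
        DatasetManifest(records=kept, tree=manifest.tree,
                        image_root=manifest.image_root),
        holdout,
    )


def measure_member_weights(
    members: Sequence[MemberModel],
    images: np.ndarray,
    truths: Sequence[Sequence[int]],
    per_level: bool = True,
) -> list[list[float]]:
    """Each member's top-1 accuracy per level on an evaluation stream.

    With ``per_level=False`` a single global weight (the mean over
    levels) is repeated across levels, matching the reading of the
    weighting rule that uses one accuracy per member.
    """
    weights = []
    for member in members:
        arrays = member.predict_arrays(images)
        accs = []
        for lvl, probs in enumerate(arrays):
            y = np.asarray([t[lvl] for t in truths])
            accs.append(float(np.mean(np.argmax(probs, axis=1) == y)))
        if not per_level:
            accs = [float(np.mean(accs))] * len(accs)
        weights.append(accs)
    return weights


def _as_level_weights(weights, n_members: int, n_levels: int) -> list[list[float]]:
    out = []
    for i in range(n_members):
        w = weights[i]
        if np.isscalar(w):
            out.append([float(w)] * n_levels)
        else:
            if len(w) != n_levels:
                raise ValueError("weights disagree with level count")
            out.append([float(v) for v in w])
    return out


def boost_combine_arrays(
    member_arrays: Sequence[Sequence[np.ndarray]],
    weights,
) -> list[np.ndarray]:
    """Weighted-sum combination on batched (N, C) arrays, renormalised
    per level so each output row sums to one."""
    n_members = len(member_arrays)
    if n_members == 0:
        raise ValueError("no members to combine")
    n_levels = len(member_arrays[0])
    shapes = [tuple(a.shape for a in m) for m in member_arrays]
    if any(s != shapes[0] for s in shapes):
        raise ValueError(f"members disagree on level sizes: {shapes}")
    w = _as_level_weights(weights, n_members, n_levels)
    if any(all(w[i][lvl] <= 0 for i in range(n_members)) for lvl in range(n_levels)):
        raise ValueError("every level needs at least one positive member weight")
    combined = []
    for lvl in range(n_levels):
        score = sum(
            w[i][lvl] * np.asarray(member_arrays[i][lvl], dtype=np.float64)
            for i in range(n_members)
        )
        combined.append(score / score.sum(axis=-1, keepdims=True))
    return combined


def boost_combine(predictions: Sequence[Sequence], weights) -> list:
    """Single-sample weighted-sum combination (one PredictionSet per
    member in, one combined PredictionSet out)."""
    member_arrays = [[np.asarray(v)[None, :] for v in p] for p in predictions]
    return [a[0] for a in boost_combine_arrays(member_arrays, weights)]


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

_LOG_EPS = 1e-12


@dataclass
class StackModel:
    """A fully connected softmax meta-layer over member outputs."""

    heads: LinearSoftmaxHeads
    n_members: int
    level_sizes: tuple[int, ...]

    @property
    def in_dim(self) -> int:
        return self.n_members * sum(self.level_sizes)

    def features(self, member_arrays: Sequence[Sequence[np.ndarray]]) -> np.ndarray:
        blocks = [
            np.log(np.asarray(a, dtype=np.float64) + _LOG_EPS)
            for m in member_arrays
            for a in m
        ]
        return np.concatenate(blocks, axis=1)

    def combine_arrays(
        self, member_arrays: Sequence[Sequence[np.ndarray]]
    ) -> list[np.ndarray]:
        return self.heads.probs(self.features(member_arrays))


def _identity_init(heads: LinearSoftmaxHeads, n_members: int,
                   level_sizes: tuple[int, ...]) -> None:
    """Each softmax group reads 1/m times every member's matching
    log-probability block, so with one member the meta-layer output
    equals the member output exactly."""
    block = 0
    offsets = []
    for _ in range(n_members):
        for c in level_sizes:
            offsets.append(block)
            block += c
    for lvl, c in enumerate(level_sizes):
        for m in range(n_members):
            off = offsets[m * len(level_sizes) + lvl]
            heads.W[lvl][off : off + c, :] = np.eye(c) / n_members


def fit_stacking(
    member_arrays: Sequence[Sequence[np.ndarray]],
    truths: Sequence[Sequence[int]],
    level_sizes: Sequence[int],
    config: TrainConfig | None = None,
    epochs: int = 200,
    init: str = "zeros",
) -> StackModel:
    """Train the meta-layer on frozen member outputs.

    ``member_arrays``: per member, per level, (N, C) probabilities on
    the meta-training stream (a held-out carve-out, never the members'
    own training data).  ``init='identity'`` starts from the
    member-averaging solution; with ``epochs=0`` that is also the
    returned model.
    """
    config = config or TrainConfig(learning_rate=0.05, batch_size=32)
    level_sizes = tuple(int(s) for s in level_sizes)
    n_members = len(member_arrays)
    for m in member_arrays:
        if tuple(a.shape[1] for a in m) != level_sizes:
            raise ValueError("members disagree on level sizes")
    stack = StackModel(
        heads=LinearSoftmaxHeads(
            n_members * sum(level_sizes), level_sizes
        ),
        n_members=n_members,
        level_sizes=level_sizes,
    )
    if init == "identity":
        _identity_init(stack.heads, n_members, level_sizes)
    elif init != "zeros":
        raise ValueError(f"unknown init {init!r}")

    feats = stack.features(member_arrays)
    ys = [np.asarray([t[lvl] for t in truths]) for lvl in range(len(level_sizes))]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    opt = Adam(stack.heads.params(), config.learning_rate)
    n = feats.shape[0]
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            _, grads = stack.heads.loss_and_grads(
                feats[idx], [y[idx] for y in ys]
            )
            opt.step(grads)
    return stack


def stack_combine(stack: StackModel, predictions: Sequence[Sequence]) -> list:
    """Apply the meta-layer to one sample's member PredictionSets."""
    member_arrays = [[np.asarray(v)[None, :] for v in p] for p in predictions]
    return [a[0] for a in stack.combine_arrays(member_arrays)]


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeSpec:
    """A router over one coarse rank plus one specialist per category.

    ``subtree_ids[c][j]`` lists, for routing category ``c``, the global
    ids at finer level ``routing_level + 1 + j`` of its descendants (in
    ascending order — the specialist's local label space).
    ``coarse_path[c]`` is the ancestor path of ``c`` at levels
    ``0..routing_level``.
    """

    tree: TaxonomyTree
    routing_level: int
    subtree_ids: dict[int, list[list[int]]]
    coarse_path: dict[int, list[int]]
    router: MultilevelClassifier | None = None
    specialists: dict[int, MultilevelClassifier] | None = None

    @property
    def n_specialists(self) -> int:
        return len(self.subtree_ids)


def plan_cascade(tree: TaxonomyTree, routing_level: int) -> CascadeSpec:
    """Derive the cascade structure (specialist label spaces and coarse
    fills) from the taxonomy, one specialist per routing category."""
    if not 0 <= routing_level < tree.n_levels:
        raise ValueError(f"routing_level {routing_level} out of range")
    subtree_ids: dict[int, list[list[int]]] = {}
    coarse_path: dict[int, list[int]] = {}
    for cat in range(tree.level_sizes[routing_level]):
        levels: list[list[int]] = []
        frontier = [cat]
        for lvl in range(routing_level, tree.n_levels - 1):
            frontier = sorted(
                c for node in frontier for c in tree.children_of(lvl, node)
            )
            levels.append(frontier)
        subtree_ids[cat] = levels
        path = [cat]
        for lvl in range(routing_level, 0, -1):
            path.append(tree.parent[lvl][path[-1]])
        coarse_path[cat] = list(reversed(path))
    return CascadeSpec(
        tree=tree,
        routing_level=routing_level,
        subtree_ids=subtree_ids,
        coarse_path=coarse_path,
    )


def _single_level_tree(tree: TaxonomyTree, level: int) -> TaxonomyTree:
    return TaxonomyTree(
        level_names=(tree.level_names[level],),
        names=(tree.names[level],),
        parent=((),),
    )


def _subtree_tree(
    tree: TaxonomyTree, routing_level: int, ids_per_level: list[list[int]]
) -> TaxonomyTree:
    """The specialist's local taxonomy over levels finer than routing."""
    level_names = tree.level_names[routing_level + 1 :]
    names = tuple(
        tuple(tree.names[routing_level + 1 + j][g] for g in ids)
        for j, ids in enumerate(ids_per_level)
    )
    parent: list[tuple[int, ...]] = [()]
    for j in range(1, len(ids_per_level)):
        gmap = {g: i for i, g in enumerate(ids_per_level[j - 1])}
        parent.append(
            tuple(
                gmap[tree.parent[routing_level + 1 + j][g]]
                for g in ids_per_level[j]
            )
        )
    return TaxonomyTree(level_names=level_names, names=names, parent=tuple(parent))


def _train_on(
    manifest: DatasetManifest,
    tree: TaxonomyTree,
    config: TrainConfig,
    backbone_factory,
) -> MultilevelClassifier:
    kind = "multilevel" if tree.n_levels > 1 else "flat"
    model = MultilevelClassifier(
        backbone_factory(), HeadLayout(kind=kind, level_sizes=tuple(tree.level_sizes))
    )
    if not manifest.split_records(config.eval_split):
        config = replace(config, eval_split="train")
    train(model, manifest, tree, config)
    return model


def build_cascade(
    manifest: DatasetManifest,
    tree: TaxonomyTree,
    routing_level: int,
    train_config: TrainConfig,
    backbone_factory=None,
) -> CascadeSpec:
    """Train the router on all train data (labelled at the routing rank)
    and one specialist per routing category on that category's records
    only, with label spaces reindexed to the subtree."""
    if backbone_factory is None:
        backbone_factory = lambda: TinyConvBackbone(
            input_resolution=train_config.resolution
        )
    spec = plan_cascade(tree, routing_level)

    counts = {c: 0 for c in spec.subtree_ids}
    for rec in manifest.records:
        if rec.split == "train":
            counts[rec.labels[routing_level]] += 1
    for cat, n in counts.items():
        if n == 0:
            raise ValueError(
                f"routing category {tree.name_of(routing_level, cat)!r} has no "
                "train records"
            )

    router_tree = _single_level_tree(tree, routing_level)
    router_manifest = DatasetManifest(
        records=[
            replace(r, labels=(r.labels[routing_level],)) for r in manifest.records
        ],
        tree=router_tree,
        image_root=manifest.image_root,
    )
    spec.router = _train_on(router_manifest, router_tree, train_config,
                            backbone_factory)

    specialists: dict[int, MultilevelClassifier] = {}
    for cat, ids_per_level in spec.subtree_ids.items():
        local_tree = _subtree_tree(tree, routing_level, ids_per_level)
        gmaps = [
            {g: i for i, g in enumerate(ids)} for ids in ids_per_level
        ]
        records = [
            replace(
                r,
                labels=tuple(
                    gmaps[j][r.labels[routing_level + 1 + j]]
                    for j in range(len(ids_per_level))
                ),
            )
            for r in manifest.records
            if r.labels[routing_level] == cat
        ]
        local_manifest = DatasetManifest(
            records=records, tree=local_tree, image_root=manifest.image_root
        )
        specialists[cat] = _train_on(
            local_manifest, local_tree, train_config, backbone_factory
        )
    spec.specialists = specialists
    return spec


def cascade_predict(spec: CascadeSpec, images: np.ndarray) -> list:
    """Route each image, then map the specialist's subtree-local
    probabilities back to global category ids (zero mass outside the
    routed subtree); ranks coarser than the routing rank are one-hot on
    the routed category's ancestors.

    Returns one PredictionSet per image over the full taxonomy.
    """
    if spec.router is None or spec.specialists is None:
        raise ValueError("cascade has not been built (router/specialists missing)")
    tree = spec.tree
    rl = spec.routing_level
    router_probs = spec.router.predict_arrays(images)[0]
    routes = np.argmax(router_probs, axis=1)

    n = images.shape[0]
    out: list[list[np.ndarray]] = [[None] * tree.n_levels for _ in range(n)]
    for i in range(n):
        for lvl in range(rl):
            vec = np.zeros(tree.level_sizes[lvl])
            vec[spec.coarse_path[routes[i]][lvl]] = 1.0
            out[i][lvl] = vec
        out[i][rl] = router_probs[i]

    for cat in sorted(set(routes.tolist())):
        idx = np.flatnonzero(routes == cat)
        local = spec.specialists[cat].predict_arrays(images[idx])
        ids_per_level = spec.subtree_ids[cat]
        for j, ids in enumerate(ids_per_level):
            lvl = rl + 1 + j
            for row, i in enumerate(idx):
                vec = np.zeros(tree.level_sizes[lvl])
                vec[ids] = local[j][row]
                out[i][lvl] = vec
    return out
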