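"""Flat and multilevel classifiers: shared convolutional features feeding
parallel per-rank softmax heads, trained with Adam on categorical
cross-entropy under periodic-evaluation early stopping.

The multilevel classifier forwards ONE shared feature vector to L
isolated fully connected layers, one per taxonomic rank; head ``i`` has
as many output neurons as rank ``i`` has categories and its own softmax.
A flat classifier is the special case of a single head over the finest
rank.  The per-level cross-entropies are combined by unweighted sum by
default (level weights are a config knob).

Backbones are pluggable behind :class:`BackboneContract`.  The default
desk-scale backbone is :class:`TinyConvBackbone`: three 3x3
convolution blocks (ReLU, 2x2 average pooling) with fixed seeded
random filters, global-average-pooled to a 64-dim feature vector.  Its
filters are frozen and only the heads are trained, the linear-probe
analogue of fine-tuning a pretrained backbone; features are therefore
computed once per image and cached, which keeps full training runs in
CPU seconds.  Trainable full-scale backbones can be plugged in through
the same contract.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple, Protocol, Sequence, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .augment import AugmentPolicy, materialize_image
from .dataio import DatasetManifest, SampleRecord
from .taxonomy import TaxonomyTree, taxonomy_from_json, taxonomy_to_json

logger = logging.getLogger("taxonet")

__all__ = [
    "softmax",
    "BackboneContract",
    "TinyConvBackbone",
    "HeadLayout",
    "TrainConfig",
    "MultilevelClassifier",
    "build_classifier",
    "multilevel_loss",
    "early_stopper",
    "EarlyStopDecision",
    "train",
    "TrainResult",
    "save_checkpoint",
    "load_checkpoint",
]

#: One image's prediction: one probability vector per head/rank.
PredictionSet = list  # list[np.ndarray]


def softmax(z: np.ndarray) -> np.ndarray:
    """Stable softmax: exp(z_i - max z) / sum_j exp(z_j - max z).

    Accepts a vector or a batch (softmax over the last axis).
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0 or z.shape[-1] == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

@runtime_checkable
class BackboneContract(Protocol):
    """What any convolutional feature extractor must provide."""

    name: str
    input_resolution: int
    feature_dim: int

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) in [0,1] -> (N, feature_dim), finite."""
        ...


class TinyConvBackbone:
    """3 conv blocks (3x3, ReLU, 2x2 avg-pool) + global average pooling.

    Filters are He-scaled Gaussian draws from a seeded generator and
    stay fixed; the backbone is a deterministic random-feature map.
    """

    def __init__(
        self,
        input_resolution: int = 32,
        feature_dim: int = 64,
        seed: int = 0,
        channels: tuple[int, ...] = (16, 32, 64),
    ) -> None:
        if channels[-1] != feature_dim:
            raise ValueError("last channel count must equal feature_dim")
        self.name = "tinyconv"
        self.input_resolution = int(input_resolution)
        self.feature_dim = int(feature_dim)
        self.seed = int(seed)
        self.channels = tuple(channels)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.filters: list[np.ndarray] = []
        c_in = 3
        for c_out in channels:
            scale = np.sqrt(2.0 / (9 * c_in))
            self.filters.append(rng.normal(0.0, scale, size=(3, 3, c_in, c_out)))
            c_in = c_out

    @staticmethod
    def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # N,H,W,C,3,3
        return np.einsum("nhwcij,ijco->nhwo", win, w, optimize=True)

    @staticmethod
    def _avg_pool2(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, : h2 * 2, : w2 * 2, :]
        return x.reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))

    def forward(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 3:
            batch = batch[None]
        out = []
        for start in range(0, len(batch), 64):
            x = batch[start : start + 64]
            for w in self.filters:
                x = np.maximum(self._conv_same(x, w), 0.0)
                x = self._avg_pool2(x)
            out.append(x.mean(axis=(1, 2)))
        feats = np.concatenate(out, axis=0)
        if not np.all(np.isfinite(feats)):
            raise FloatingPointError("backbone produced non-finite features")
        return feats

    def meta(self) -> dict:
        return {
            "name": self.name,
            "input_resolution": self.input_resolution,
            "feature_dim": self.feature_dim,
            "seed": self.seed,
            "channels": list(self.channels),
        }


# ---------------------------------------------------------------------------
# Heads and classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadLayout:
    """``flat`` uses a single head over the finest rank; ``multilevel``
    one head per rank."""

    kind: str
    level_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "multilevel"):
            raise ValueError(f"kind must be flat|multilevel, got {self.kind!r}")
        if not self.level_sizes or any(s < 1 for s in self.level_sizes):
            raise ValueError("level_sizes must be positive")

    @property
    def head_sizes(self) -> tuple[int, ...]:
        return (
            (self.level_sizes[-1],) if self.kind == "flat" else self.level_sizes
        )

    @property
    def head_levels(self) -> tuple[int, ...]:
        """Taxonomy level index each head predicts."""
        n = len(self.level_sizes)
        return (n - 1,) if self.kind == "flat" else tuple(range(n))


class LinearSoftmaxHeads:
    """Parallel fully connected softmax groups over one input vector.

    Used both for the classifier heads (input = backbone features) and
    for the stacking meta-layer (input = concatenated member outputs).
    """

    def __init__(
        self,
        in_dim: int,
        group_sizes: Sequence[int],
        weights: list[np.ndarray] | None = None,
        biases: list[np.ndarray] | None = None,
    ) -> None:
        self.in_dim = int(in_dim)
        self.group_sizes = tuple(int(s) for s in group_sizes)
        if weights is None:
            weights = [np.zeros((in_dim, s)) for s in self.group_sizes]
            biases = [np.zeros(s) for s in self.group_sizes]
        self.W = weights
        self.b = biases

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def logits(self, feats: np.ndarray) -> list[np.ndarray]:
        return [feats @ w + b for w, b in zip(self.W, self.b)]

    def probs(self, feats: np.ndarray) -> list[np.ndarray]:
        return [softmax(z) for z in self.logits(feats)]

    def loss_and_grads(
        self,
        feats: np.ndarray,
        truths: Sequence[np.ndarray],
        level_weights: Sequence[float] | None = None,
    ) -> tuple[float, list[np.ndarray]]:
        """Mean weighted-sum cross-entropy over the batch and its
        gradients in params() order."""
        n = feats.shape[0]
        if level_weights is None:
            level_weights = [1.0] * len(self.group_sizes)
        loss = 0.0
        gw, gb = [], []
        for w_lvl, z, y in zip(level_weights, self.logits(feats), truths):
            p = softmax(z)
            loss += w_lvl * -np.log(
                np.maximum(p[np.arange(n), y], 1e-300)
            ).mean()
            delta = p.copy()
            delta[np.arange(n), y] -= 1.0
            delta *= w_lvl / n
            gw.append(feats.T @ delta)
            gb.append(delta.sum(axis=0))
        return float(loss), gw + gb

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]


class MultilevelClassifier:
    """A backbone plus flat or per-rank softmax heads.

    Backbone features are standardized (per-dimension zero mean, unit
    variance, statistics frozen from the training split) before the
    heads, which conditions the head optimisation independently of the
    backbone's activation scale.
    """

    def __init__(self, backbone: BackboneContract, layout: HeadLayout) -> None:
        self.backbone = backbone
        self.layout = layout
        self.heads = LinearSoftmaxHeads(backbone.feature_dim, layout.head_sizes)
        self.feat_mean: np.ndarray | None = None
        self.feat_scale: np.ndarray | None = None

    @property
    def head_levels(self) -> tuple[int, ...]:
        return self.layout.head_levels

    def fit_feature_norm(self, feats: np.ndarray) -> None:
        self.feat_mean = feats.mean(axis=0)
        self.feat_scale = np.maximum(feats.std(axis=0), 1e-8)

    def transform_features(self, feats: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return feats
        return (feats - self.feat_mean) / self.feat_scale

    def features(self, images: np.ndarray) -> np.ndarray:
        return self.transform_features(self.backbone.forward(images))

    def predict_arrays(self, images: np.ndarray) -> list[np.ndarray]:
        """Per-head (N, C) probability arrays."""
        return self.heads.probs(self.features(images))

    def predict(self, images: np.ndarray) -> list[PredictionSet]:
        """One PredictionSet (list of per-head vectors) per image."""
        arrays = self.predict_arrays(images)
        n = arrays[0].shape[0]
        return [[a[i] for a in arrays] for i in range(n)]


def build_classifier(
    backbone: BackboneContract, layout: HeadLayout, tree: TaxonomyTree | None = None
) -> MultilevelClassifier:
    """Construct the classifier, checking the layout against a taxonomy."""
    if tree is not None and tuple(layout.level_sizes) != tuple(tree.level_sizes):
        raise ValueError(
            f"layout level_sizes {layout.level_sizes} disagree with taxonomy "
            f"{tree.level_sizes}"
        )
    return MultilevelClassifier(backbone, layout)


def multilevel_loss(pred: PredictionSet, truth: Sequence[int]) -> float:
    """Sum over heads of -log p_head[true class] (equal level weights)."""
    if len(pred) != len(truth):
        raise ValueError("prediction and truth disagree on level count")
    total = 0.0
    for p, t in zip(pred, truth):
        p = np.asarray(p)
        if not 0 <= t < p.shape[0]:
            raise IndexError(f"truth index {t} out of range for {p.shape[0]} classes")
        total += -float(np.log(max(p[t], 1e-300)))
    return total


# ---------------------------------------------------------------------------
# Optimisation and early stopping
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam (optionally AMSGrad) over a flat parameter list."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        amsgrad: bool = False,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.amsgrad = amsgrad
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.vhat = [np.zeros_like(p) for p in params] if amsgrad else None
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            v = self.v[i] / (1 - self.b2**self.t)
            if self.amsgrad:
                self.vhat[i] = np.maximum(self.vhat[i], v)
                v = self.vhat[i]
            p -= self.lr * mhat / (np.sqrt(v) + self.eps)


class EarlyStopDecision(NamedTuple):
    best_index: int
    halt_index: int | None


def early_stopper(
    accuracy_trace: Sequence[float], patience: int, min_delta: float = 0.0
) -> EarlyStopDecision:
    """Scan an evaluation trace for the halting point.

    Training halts at the evaluation after which ``patience``
    consecutive evaluations have failed to exceed the best-so-far by
    more than ``min_delta``; the best checkpoint index is returned
    alongside.  ``halt_index`` is None if the trace never triggers.
    """
    best = -np.inf
    best_index = 0
    since_best = 0
    for i, acc in enumerate(accuracy_trace):
        if acc > best + min_delta:
            best, best_index, since_best = acc, i, 0
        else:
            since_best += 1
        if since_best >= patience:
            return EarlyStopDecision(best_index, i)
    return EarlyStopDecision(best_index, None)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the reference protocol:
    Adam at 1e-4, cross-entropy, a test every 10 epochs, patience of 10
    tests)."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    test_interval_epochs: int = 10
    patience_tests: int = 10
    min_delta: float = 0.0
    seed: int = 0
    resolution: int = 32
    max_epochs: int = 10_000
    amsgrad: bool = False
    level_weights: tuple[float, ...] | None = None
    eval_split: str = "test"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.test_interval_epochs < 1 or self.patience_tests < 0:
            raise ValueError("intervals must be positive")


@dataclass
class TrainResult:
    model: MultilevelClassifier
    log: list[dict]
    monitor_trace: list[float]
    best_test_index: int
    halted_at: int | None


def _dataset_features(
    records: list[SampleRecord],
    model: MultilevelClassifier,
    manifest: DatasetManifest,
    config: TrainConfig,
    policy: AugmentPolicy | None,
) -> np.ndarray:
    policy = policy or AugmentPolicy(mode="standard")
    images = np.stack(
        [
            materialize_image(
                rec, policy, config.resolution, image_root=manifest.image_root
            )
            for rec in records
        ]
    )
    return model.backbone.forward(images)


def _topk_hits(probs: np.ndarray, truths: np.ndarray, k: int) -> float:
    order = np.argsort(-probs, axis=1, kind="stable")[:, :k]
    return float(np.mean([t in row for t, row in zip(truths, order)]))


def train(
    model: MultilevelClassifier,
    manifest: DatasetManifest,
    tree: TaxonomyTree,
    config: TrainConfig,
    policy: AugmentPolicy | None = None,
) -> TrainResult:
    """Fit the heads with Adam under the periodic-test early-stopping
    protocol; returns the best-checkpoint model plus the training log.

    The loop is nominally unbounded ("train forever, early-stop"), with
    ``max_epochs`` as a safety cap.  Evaluation runs on the configured
    split every ``test_interval_epochs`` epochs; the monitored quantity
    is finest-head top-1.
    """
    train_recs = manifest.split_records("train")
    eval_recs = manifest.split_records(config.eval_split)
    if not train_recs:
        raise ValueError("train split is empty")
    if not eval_recs:
        raise ValueError(f"{config.eval_split} split is empty")
    if config.eval_split == "test":
        logger.warning(
            "early stopping monitors the test split (reference protocol); "
            "use a validation carve-out for unbiased model selection"
        )

    head_levels = model.head_levels
    feats_train = _dataset_features(train_recs, model, manifest, config, policy)
    feats_eval = _dataset_features(eval_recs, model, manifest, config, policy)
    model.fit_feature_norm(feats_train)
    feats_train = model.transform_features(feats_train)
    feats_eval = model.transform_features(feats_eval)
    y_train = [
        np.array([r.labels[lvl] for r in train_recs]) for lvl in head_levels
    ]
    y_eval = [
        np.array([r.labels[lvl] for r in eval_recs]) for lvl in head_levels
    ]

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    opt = Adam(model.heads.params(), config.learning_rate, amsgrad=config.amsgrad)
    n = feats_train.shape[0]
    log: list[dict] = []
    trace: list[float] = []
    best_params = model.heads.copy_params()
    halted_at = None

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            _, grads = model.heads.loss_and_grads(
                feats_train[idx],
                [y[idx] for y in y_train],
                config.level_weights,
            )
            opt.step(grads)

        if epoch % config.test_interval_epochs == 0:
            probs = model.heads.probs(feats_eval)
            loss, _ = model.heads.loss_and_grads(
                feats_eval, y_eval, config.level_weights
            )
            for h, lvl in enumerate(head_levels):
                c = probs[h].shape[1]
                log.append(
                    {
                        "test_index": len(trace),
                        "epoch": epoch,
                        "level_name": tree.level_names[lvl],
                        "top1": _topk_hits(probs[h], y_eval[h], 1),
                        "top5": _topk_hits(probs[h], y_eval[h], min(5, c)),
                        "loss": loss,
                    }
                )
            monitor = _topk_hits(probs[-1], y_eval[-1], 1)
            trace.append(monitor)
            decision = early_stopper(trace, config.patience_tests, config.min_delta)
            if decision.best_index == len(trace) - 1:
                best_params = model.heads.copy_params()
            if decision.halt_index is not None:
                halted_at = decision.halt_index
                break

    final = early_stopper(trace, config.patience_tests, config.min_delta)
    model.heads.set_params(best_params)
    return TrainResult(
        model=model,
        log=log,
        monitor_trace=trace,
        best_test_index=final.best_index,
        halted_at=halted_at,
    )


def write_training_log(log: list[dict], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["test_index", "epoch", "level_name", "top1", "top5", "loss"]
        )
        writer.writeheader()
        writer.writerows(log)


# ---------------------------------------------------------------------------
# Checkpoints: a single self-describing zip (weights + layout + taxonomy
# + training config)
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    model: MultilevelClassifier,
    tree: TaxonomyTree,
    config: TrainConfig | None = None,
) -> None:
    meta = {
        "layout": {"kind": model.layout.kind,
                   "level_sizes": list(model.layout.level_sizes)},
        "backbone": model.backbone.meta(),
        "taxonomy": json.loads(taxonomy_to_json(tree)),
        "config": asdict(config) if config else None,
        "n_heads": len(model.heads.W),
    }
    meta["has_feature_norm"] = model.feat_mean is not None
    arrays: list[tuple[str, np.ndarray]] = []
    for i, (w, b) in enumerate(zip(model.heads.W, model.heads.b)):
        arrays += [(f"head{i}_W.npy", w), (f"head{i}_b.npy", b)]
    if model.feat_mean is not None:
        arrays += [("feat_mean.npy", model.feat_mean),
                   ("feat_scale.npy", model.feat_scale)]
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for name, arr in arrays:
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name, buf.getvalue())


def load_checkpoint(
    path: str | Path,
) -> tuple[MultilevelClassifier, TaxonomyTree, TrainConfig | None]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        bmeta = meta["backbone"]
        if bmeta["name"] != "tinyconv":
            raise ValueError(
                f"unknown backbone {bmeta['name']!r}; plug-in backbones must be "
                "reconstructed by the caller"
            )
        backbone = TinyConvBackbone(
            input_resolution=bmeta["input_resolution"],
            feature_dim=bmeta["feature_dim"],
            seed=bmeta["seed"],
            channels=tuple(bmeta["channels"]),
        )
        layout = HeadLayout(
            kind=meta["layout"]["kind"],
            level_sizes=tuple(meta["layout"]["level_sizes"]),
        )
        model = MultilevelClassifier(backbone, layout)
        for i in range(meta["n_heads"]):
            model.heads.W[i] = np.load(io.BytesIO(zf.read(f"head{i}_W.npy")))
            model.heads.b[i] = np.load(io.BytesIO(zf.read(f"head{i}_b.npy")))
        if meta.get("has_feature_norm"):
            model.feat_mean = np.load(io.BytesIO(zf.read("feat_mean.npy")))
            model.feat_scale = np.load(io.BytesIO(zf.read("feat_scale.npy")))
        tree = taxonomy_from_json(json.dumps(meta["taxonomy"]))
        config = TrainConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["config"].items()
        }) if meta["config"] else None
    return model, tree, config
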