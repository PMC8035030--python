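"""Per-level evaluation: top-k accuracy, per-class and weighted F1,
macro one-vs-rest ROC AUC, and the normal fit to the per-class F1
distribution.

Conventions (fixed across the package): argmax/top-k ties break toward
the lowest category id; the normal fit uses the population standard
deviation (divide by n) by default, with the sample convention behind a
flag; AUC is macro-averaged one-vs-rest over classes that have at least
one positive and one negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

__all__ = [
    "topk_accuracy",
    "per_class_f1",
    "fit_f1_normal",
    "auc_score",
    "EvalReport",
    "evaluate_predictions",
]


def _level_matrix(predictions: Sequence, level: int) -> np.ndarray:
    """Stack one level's probability vectors from a list of
    PredictionSets into an (N, C) array."""
    return np.asarray([np.asarray(p[level], dtype=np.float64) for p in predictions])


def _truth_vector(truths: Sequence, level: int) -> np.ndarray:
    return np.asarray([t[level] for t in truths], dtype=int)


def topk_accuracy(
    predictions: Sequence, truths: Sequence, k: int, level: int
) -> float:
    """Fraction of samples whose true category at ``level`` is among the
    k highest-probability categories (ties: lowest id first)."""
    probs = _level_matrix(predictions, level)
    y = _truth_vector(truths, level)
    n, c = probs.shape
    if not 1 <= k <= c:
        raise ValueError(f"k must lie in [1, {c}], got {k}")
    # stable argsort on -p keeps lower ids first among ties
    order = np.argsort(-probs, axis=1, kind="stable")[:, :k]
    return float(np.mean(np.any(order == y[:, None], axis=1)))


def per_class_f1(
    predictions: Sequence, truths: Sequence, level: int
) -> tuple[np.ndarray, float]:
    """One-vs-rest precision/recall/F1 from argmax decisions.

    Returns the per-class F1 vector (all classes, in id order) and the
    support-weighted mean over classes with non-zero support.
    """
    probs = _level_matrix(predictions, level)
    if probs.shape[0] == 0:
        raise ValueError("no predictions to evaluate")
    y = _truth_vector(truths, level)
    y_pred = np.argmax(probs, axis=1)  # first (lowest-id) max
    labels = np.arange(probs.shape[1])
    _, _, f1, support = precision_recall_fscore_support(
        y, y_pred, labels=labels, zero_division=0
    )
    mask = support > 0
    weighted = float(np.average(f1[mask], weights=support[mask]))
    return f1, weighted


def fit_f1_normal(
    per_class_f1_values: Sequence[float], sample_sd: bool = False
) -> dict:
    """Fit a normal to the per-class F1 distribution.

    Returns mu (mean), sigma (population sd by default) and the
    empirical coverage fractions within one and two sigma.
    """
    values = np.asarray(per_class_f1_values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 classes to fit a spread")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1 if sample_sd else 0))
    within = lambda s: float(
        np.mean((values >= mu - s * sigma) & (values <= mu + s * sigma))
    )
    return {
        "mu": mu,
        "sigma": sigma,
        "within_1sigma": within(1.0),
        "within_2sigma": within(2.0),
    }


def auc_score(predictions: Sequence, truths: Sequence, level: int) -> float:
    """Macro-averaged one-vs-rest ROC AUC over evaluable classes."""
    probs = _level_matrix(predictions, level)
    y = _truth_vector(truths, level)
    n, c = probs.shape
    if c < 2:
        raise ValueError("AUC undefined for a single-class level")
    aucs = []
    for cls in range(c):
        pos = y == cls
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos.astype(int), probs[:, cls]))
    if not aucs:
        raise ValueError("no class has both positives and negatives")
    return float(np.mean(aucs))


@dataclass
class EvalReport:
    """Per-level top-k plus finest-level class diagnostics."""

    level_names: tuple[str, ...]
    top1: list[float]
    top5: list[float]
    per_class_f1: list[float]
    weighted_f1: float
    auc: float | None
    f1_normal_fit: dict

    def __post_init__(self) -> None:
        for t1, t5 in zip(self.top1, self.top5):
            if not 0.0 <= t1 <= t5 <= 1.0:
                raise ValueError(f"need 0 <= top1 <= top5 <= 1, got {t1}, {t5}")

    def to_json(self) -> str:
        from dataclasses import asdict

        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, doc: str) -> "EvalReport":
        data = json.loads(doc)
        data["level_names"] = tuple(data["level_names"])
        return cls(**data)

    def write(self, out_dir: str | Path, stem: str = "report") -> None:
        """JSON + per-level CSV + finest-level per-class CSV."""
        import csv

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{stem}.json").write_text(self.to_json())
        with open(out_dir / f"{stem}_levels.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["level_name", "top1", "top5"])
            for name, t1, t5 in zip(self.level_names, self.top1, self.top5):
                w.writerow([name, t1, t5])
        with open(out_dir / f"{stem}_per_class.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class_id", "f1"])
            for cid, f1 in enumerate(self.per_class_f1):
                w.writerow([cid, f1])


def evaluate_predictions(
    predictions: Sequence,
    truths: Sequence,
    level_names: Sequence[str],
) -> EvalReport:
    """Full report over a list of PredictionSets and truth label vectors.

    top-5 falls back to k = level size where a level has fewer than 5
    categories; AUC is omitted (None) for single-class finest levels.
    """
    n_levels = len(level_names)
    top1, top5 = [], []
    for lvl in range(n_levels):
        c = np.asarray(predictions[0][lvl]).shape[0]
        top1.append(topk_accuracy(predictions, truths, 1, lvl))
        top5.append(topk_accuracy(predictions, truths, min(5, c), lvl))
    finest = n_levels - 1
    f1, weighted = per_class_f1(predictions, truths, finest)
    try:
        auc = auc_score(predictions, truths, finest)
    except ValueError:
        auc = None
    fit = (
        fit_f1_normal(f1)
        if f1.size >= 2
        else {"mu": float(f1[0]), "sigma": 0.0,
              "within_1sigma": 1.0, "within_2sigma": 1.0}
    )
    return EvalReport(
        level_names=tuple(level_names),
        top1=top1,
        top5=top5,
        per_class_f1=[float(v) for v in f1],
        weighted_f1=weighted,
        auc=auc,
        f1_normal_fit=fit,
    )
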