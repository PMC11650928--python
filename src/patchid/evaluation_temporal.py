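"""Image-based and shark-based evaluation, ROC/AUC, temporal stability.

Image-based evaluation scores one decision per image pair. Shark-based
evaluation scores one decision per *group* pair: for two groups of K1 and K2
images, all K1 x K2 cross-group final indices are averaged into a single
score before the 0.5 rule is applied. Same-shark (positive) group instances
are formed by halving each group with at least two images.

MAE is computed on the binarized decisions, so every report satisfies
accuracy + MAE = 1 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations_io import parse_time_marker
from .ensemble_fusion import EnsembleModel, collect_indices, decide, final_similarity
from .exceptions import ConfigError
from .patch_pipeline import Patch
from .similarity_net import EmbeddingCache, PatchModel

__all__ = [
    "ImagePair",
    "SharkGroup",
    "EvaluationReport",
    "confusion_metrics",
    "roc_auc",
    "image_based_eval",
    "shark_based_eval",
    "temporal_analysis",
    "report_from_scores",
]

#: One image = its four patches keyed by patch type.
PatchSet = Mapping[str, Patch]


@dataclass(frozen=True)
class ImagePair:
    """Two images (as patch sets) plus the same-individual label."""

    patches_a: PatchSet
    patches_b: PatchSet
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ConfigError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class SharkGroup:
    """All images confidently assigned to one individual."""

    shark_id: str
    images: tuple[PatchSet, ...]

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ConfigError(f"group {self.shark_id!r} has zero images")

    @property
    def K(self) -> int:
        return len(self.images)


@dataclass
class EvaluationReport:
    n_pairs: int
    accuracy: float
    precision: float  # NaN when undefined
    precision_defined: bool
    mae: float
    scores: list[float] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "accuracy": self.accuracy,
            "precision": None if not self.precision_defined else self.precision,
            "precision_defined": self.precision_defined,
            "mae": self.mae,
            "auc": self.auc,
            "roc": self.roc,
        }


def confusion_metrics(
    decisions: Sequence[int], labels: Sequence[int]
) -> tuple[float, float, float]:
    """(accuracy, precision, MAE) of binary decisions against binary labels.

    Positive means "same individual". Precision is NaN when there are no
    positive predictions. MAE = mean |decision - label| = 1 - accuracy.
    """
    d = np.asarray(decisions, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if d.shape != y.shape or d.ndim != 1 or len(d) < 1:
        raise ConfigError("decisions and labels must be equal-length nonempty vectors")
    accuracy = float(np.mean(d == y))
    mae = float(np.mean(np.abs(d - y)))
    n_pred_pos = int(np.sum(d == 1))
    if n_pred_pos == 0:
        precision = float("nan")
    else:
        precision = float(np.sum((d == 1) & (y == 1)) / n_pred_pos)
    return accuracy, precision, mae


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points over all distinct thresholds and the trapezoid AUC.

    Equal scores are grouped per threshold, so the trapezoid area equals
    P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if s.shape != y.shape or s.ndim != 1:
        raise ConfigError("scores and labels must be equal-length vectors")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(np.sum(y_sorted[i:j] == 1))
        fp += int(np.sum(y_sorted[i:j] == 0))
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auc)


def report_from_scores(scores: list[float], labels: list[int]) -> EvaluationReport:
    decisions = [1 if decide(v) == "same" else 0 for v in scores]
    accuracy, precision, mae = confusion_metrics(decisions, labels)
    roc = auc = None
    if 0 < sum(labels) < len(labels):
        roc, auc = roc_auc(scores, labels)
    return EvaluationReport(
        n_pairs=len(scores),
        accuracy=accuracy,
        precision=precision,
        precision_defined=not math.isnan(precision),
        mae=mae,
        scores=scores,
        labels=labels,
        roc=roc,
        auc=auc,
    )


def image_based_eval(
    patch_models: Mapping[str, PatchModel],
    ensemble: EnsembleModel,
    pairs: Sequence[ImagePair],
    cache: EmbeddingCache | None = None,
) -> EvaluationReport:
    """Score every image pair independently and report the metrics."""
    if len(pairs) == 0:
        raise ConfigError("empty image-pair set")
    if cache is None:
        cache = EmbeddingCache()
    scores = [
        float(final_similarity(ensemble, collect_indices(patch_models, p.patches_a, p.patches_b, cache=cache)))
        for p in pairs
    ]
    return report_from_scores(scores, [p.label for p in pairs])


def _cross_score(
    patch_models: Mapping[str, PatchModel],
    ensemble: EnsembleModel,
    images_a: Sequence[PatchSet],
    images_b: Sequence[PatchSet],
    cache: EmbeddingCache,
) -> float:
    """Mean final index over all K1 x K2 ordered cross-group image pairs."""
    vals = [
        float(final_similarity(ensemble, collect_indices(patch_models, pa, pb, cache=cache)))
        for pa in images_a
        for pb in images_b
    ]
    return float(np.mean(vals))


def shark_based_eval(
    patch_models: Mapping[str, PatchModel],
    ensemble: EnsembleModel,
    groups: Sequence[SharkGroup],
    cache: EmbeddingCache | None = None,
) -> EvaluationReport:
    """Group-level evaluation by K1 x K2 score averaging.

    Negative instances: every unordered pair of groups (assumed different
    individuals when their shark_ids differ). Positive instances: each group
    with >= 2 images, split into two halves compared against each other.
    """
    if len(groups) < 2:
        raise ConfigError("shark-based evaluation needs at least two groups")
    if cache is None:
        cache = EmbeddingCache()
    scores: list[float] = []
    labels: list[int] = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            scores.append(_cross_score(patch_models, ensemble, gi.images, gj.images, cache))
            labels.append(1 if gi.shark_id == gj.shark_id else 0)
    for g in groups:
        if g.K >= 2:
            half = g.K // 2
            scores.append(
                _cross_score(patch_models, ensemble, g.images[:half], g.images[half:], cache)
            )
            labels.append(1)
    return report_from_scores(scores, labels)


def temporal_analysis(
    patch_models: Mapping[str, PatchModel],
    ensemble: EnsembleModel,
    baseline: SharkGroup,
    time_groups: Mapping[str, Sequence[PatchSet]],
    cache: EmbeddingCache | None = None,
) -> tuple[list[tuple[str, float]], str]:
    """Shark-based similarity of each time marker against the baseline group.

    Returns the per-marker average final indices (markers ordered by numeric
    suffix) and the verdict: "stable" iff every marker scores strictly above
    0.5, else "unstable".
    """
    if baseline.K < 1:
        raise ConfigError("baseline group is empty")
    if not time_groups:
        raise ConfigError("no time markers given")
    if cache is None:
        cache = EmbeddingCache()
    markers = sorted(time_groups, key=parse_time_marker)
    curve: list[tuple[str, float]] = []
    for marker in markers:
        images = list(time_groups[marker])
        if not images:
            raise ConfigError(f"time marker {marker} has no images")
        score = _cross_score(patch_models, ensemble, images, baseline.images, cache)
        curve.append((marker, score))
    verdict = "stable" if all(v > 0.5 for _, v in curve) else "unstable"
    return curve, verdict
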