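"""Per-patch twin network: frozen backbone, average pooling, trainable head.

Both branches share one frozen backbone (the twin contract). Each branch's
feature map is averaged over all spatial positions to one value per channel;
the two pooled embeddings are concatenated and passed through a 32-unit ReLU
dense layer and a 1-unit sigmoid layer. The sigmoid output is the similarity
index s in (0, 1) — the modelled probability that the two patches come from
the same individual. Only the two dense layers train; the backbone stays
bit-identical.

Note the concatenation is ordered, so s(a, b) != s(b, a) in general; the
asymmetry is intentional and preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations_io import PATCH_TYPES
from .backbones import Backbone, TinyConvBackbone
from .exceptions import ConfigError, FormatError
from .pairs_and_splits import PairSample
from .patch_pipeline import Patch, preprocess_for_backbone

__all__ = [
    "SimilarityHead",
    "PatchModel",
    "init_head",
    "embed",
    "similarity",
    "train_head",
    "save_model",
    "load_model",
    "EmbeddingCache",
]

HIDDEN_UNITS = 32
_FORMAT_VERSION = 1


@dataclass
class SimilarityHead:
    """Trainable top: dense (2F -> 32, ReLU) then dense (32 -> 1, sigmoid)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def forward(self, z: np.ndarray) -> np.ndarray:
        """Similarity indices for a (N, 2F) batch of concatenated embeddings."""
        from scipy.special import expit

        h = np.maximum(z @ self.W1 + self.b1, 0.0)
        logits = h @ self.W2 + self.b2
        return expit(logits[:, 0])

    def copy(self) -> "SimilarityHead":
        return SimilarityHead(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())


def init_head(feature_dim: int, rng: np.random.Generator, hidden: int = HIDDEN_UNITS) -> SimilarityHead:
    """Glorot-initialized head for embeddings of length ``feature_dim``."""
    n_in = 2 * feature_dim
    lim1 = np.sqrt(6.0 / (n_in + hidden))
    lim2 = np.sqrt(6.0 / (hidden + 1))
    return SimilarityHead(
        W1=rng.uniform(-lim1, lim1, size=(n_in, hidden)),
        b1=np.zeros(hidden),
        W2=rng.uniform(-lim2, lim2, size=(hidden, 1)),
        b2=np.zeros(1),
    )


@dataclass
class PatchModel:
    """One patch type's twin model: shared frozen backbone + trainable head."""

    patch_type: str
    backbone: Backbone
    head: SimilarityHead

    def __post_init__(self) -> None:
        if self.patch_type not in PATCH_TYPES:
            raise ConfigError(f"unknown patch type {self.patch_type!r}")


def embed(model: PatchModel, preprocessed: np.ndarray) -> np.ndarray:
    """Average-pool the backbone feature map: one value per channel.

    ``preprocessed`` is a single (side, side, 3) array or an (N, side, side, 3)
    batch already mapped to the backbone's input contract.
    """
    x = np.asarray(preprocessed, dtype=np.float64)
    single = x.ndim == 3
    if single:
        x = x[None]
    fmap = model.backbone.forward(x)
    pooled = fmap.mean(axis=(1, 2))
    return pooled[0] if single else pooled


def _embed_patch(model: PatchModel, patch: Patch) -> np.ndarray:
    return embed(model, preprocess_for_backbone(patch, model.backbone.spec))


class EmbeddingCache:
    """Memoizes patch embeddings per model within one evaluation run."""

    def __init__(self) -> None:
        self._store: dict[tuple[int, int], np.ndarray] = {}

    def embedding(self, model: PatchModel, patch: Patch) -> np.ndarray:
        key = (id(model), id(patch))
        hit = self._store.get(key)
        if hit is None:
            hit = self._store[key] = _embed_patch(model, patch)
        return hit


def similarity(
    model: PatchModel,
    patch_a: Patch,
    patch_b: Patch,
    cache: EmbeddingCache | None = None,
) -> float:
    """Similarity index s in (0, 1) for an ordered patch pair."""
    for p in (patch_a, patch_b):
        if p.patch_type != model.patch_type:
            raise ConfigError(
                f"patch type {p.patch_type!r} does not match model {model.patch_type!r}"
            )
    if cache is not None:
        ea = cache.embedding(model, patch_a)
        eb = cache.embedding(model, patch_b)
    else:
        ea = _embed_patch(model, patch_a)
        eb = _embed_patch(model, patch_b)
    z = np.concatenate([ea, eb])[None, :]
    return float(model.head.forward(z)[0])


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def train_head(
    model: PatchModel,
    pairs: Sequence[PairSample],
    epochs: int = 50,
    learning_rate: float = 1e-3,
    rng: np.random.Generator | None = None,
    batch_size: int = 16,
    optimizer: str = "sgd",
    embed_chunk: int = 256,
) -> tuple[PatchModel, list[float]]:
    """Train only the head on labelled pairs with mini-batch gradient descent.

    Embeddings are computed once through the frozen backbone (its weights are
    bit-identical before and after). Internally the concatenated embeddings
    are standardized for conditioning; the affine standardization is folded
    back into the first dense layer, so the returned head honours the plain
    dense-dense contract. ``optimizer`` is "sgd" (default) or "adam".
    """
    if rng is None:
        rng = np.random.default_rng()
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ConfigError("training pairs must contain both classes")
    if optimizer not in ("sgd", "adam"):
        raise ConfigError(f"unknown optimizer {optimizer!r}")
    for p in pairs:
        if p.patch_type != model.patch_type:
            raise ConfigError("pair patch type does not match model")

    # embed every distinct patch exactly once
    uniq: dict[int, Patch] = {}
    for p in pairs:
        uniq.setdefault(id(p.patch_a), p.patch_a)
        uniq.setdefault(id(p.patch_b), p.patch_b)
    keys = list(uniq)
    emb: dict[int, np.ndarray] = {}
    spec = model.backbone.spec
    for start in range(0, len(keys), embed_chunk):
        chunk = keys[start : start + embed_chunk]
        stack = np.stack([preprocess_for_backbone(uniq[k], spec) for k in chunk])
        pooled = embed(model, stack)
        for k, e in zip(chunk, pooled):
            emb[k] = e

    Z = np.stack([np.concatenate([emb[id(p.patch_a)], emb[id(p.patch_b)]]) for p in pairs])
    y = np.array([p.label for p in pairs], dtype=np.float64)

    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd < 1e-8] = 1.0
    Zs = (Z - mu) / sd

    feature_dim = Z.shape[1] // 2
    head = init_head(feature_dim, rng)
    W1, b1, W2, b2 = head.W1, head.b1, head.W2, head.b2

    if optimizer == "adam":
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m = [np.zeros_like(w) for w in (W1, b1, W2, b2)]
        v = [np.zeros_like(w) for w in (W1, b1, W2, b2)]
        step = 0

    checksum_before = model.backbone.weight_checksum()
    history: list[float] = []
    index_pairs = list(range(len(pairs)))
    for _epoch in range(epochs):
        order = rng.permutation(len(index_pairs))
        epoch_losses = []
        for start in range(0, len(order), batch_size):
            sel = order[start : start + batch_size]
            zb, yb = Zs[sel], y[sel]
            h_pre = zb @ W1 + b1
            h = np.maximum(h_pre, 0.0)
            logits = (h @ W2 + b2)[:, 0]
            s = 1.0 / (1.0 + np.exp(-logits))
            epoch_losses.append(_bce(s, yb))
            d = (s - yb)[:, None] / len(sel)
            gW2 = h.T @ d
            gb2 = d.sum(axis=0)
            dh = (d @ W2.T) * (h_pre > 0)
            gW1 = zb.T @ dh
            gb1 = dh.sum(axis=0)
            grads = (gW1, gb1, gW2, gb2)
            if optimizer == "sgd":
                W1 -= learning_rate * gW1
                b1 -= learning_rate * gb1
                W2 -= learning_rate * gW2
                b2 -= learning_rate * gb2
            else:
                step += 1
                params = (W1, b1, W2, b2)
                for i, (w, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**step)
                    vhat = v[i] / (1 - beta2**step)
                    w -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.append(float(np.mean(epoch_losses)))

    if model.backbone.weight_checksum() != checksum_before:
        raise ConfigError("backbone weights changed during head training")

    # fold the standardization into the first dense layer
    W1_eff = W1 / sd[:, None]
    b1_eff = b1 - (mu / sd) @ W1
    model.head = SimilarityHead(W1_eff, b1_eff, W2, b2)
    return model, history


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: PatchModel, path: str | Path) -> None:
    """Write a model directory: spec.json + weights.npz."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    bspec = model.backbone.spec
    spec = {
        "format_version": _FORMAT_VERSION,
        "patch_type": model.patch_type,
        "backbone": {
            "name": bspec.name,
            "provenance": bspec.provenance,
            "input_side": bspec.input_side,
            "input_range": list(bspec.input_range),
            "feature_dim": bspec.feature_dim,
            "seed": getattr(model.backbone, "seed", None),
            "checksum": model.backbone.weight_checksum(),
        },
    }
    (out / "spec.json").write_text(json.dumps(spec, indent=2))
    np.savez(
        out / "weights.npz",
        W1=model.head.W1,
        b1=model.head.b1,
        W2=model.head.W2,
        b2=model.head.b2,
    )


def load_model(path: str | Path, expect_patch_type: str | None = None) -> PatchModel:
    """Load a model directory written by :func:`save_model`."""
    root = Path(path)
    spec_path = root / "spec.json"
    if not spec_path.exists():
        raise FormatError(f"{root}: no spec.json")
    spec = json.loads(spec_path.read_text())
    if spec.get("format_version") != _FORMAT_VERSION:
        raise FormatError(f"{root}: unsupported format version {spec.get('format_version')}")
    bspec = spec.get("backbone")
    if not bspec:
        raise FormatError(f"{root}: model file has no backbone spec")
    if expect_patch_type is not None and spec["patch_type"] != expect_patch_type:
        raise FormatError(
            f"{root}: model is for patch type {spec['patch_type']!r}, "
            f"expected {expect_patch_type!r}"
        )
    if bspec["provenance"] == "random_frozen_test":
        backbone = TinyConvBackbone(seed=int(bspec["seed"]))
        if backbone.weight_checksum() != bspec["checksum"]:
            raise FormatError(f"{root}: backbone checksum mismatch")
    else:
        raise FormatError(
            f"{root}: backbone {bspec['name']!r} requires pretrained reference weights, "
            "which are not distributable with this package"
        )
    with np.load(root / "weights.npz") as wz:
        head = SimilarityHead(W1=wz["W1"], b1=wz["b1"], W2=wz["W2"], b2=wz["b2"])
    return PatchModel(patch_type=spec["patch_type"], backbone=backbone, head=head)
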