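"""Held-out-individual splits, labelled pair generation and batching."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .annotations_io import LIFE_STAGES, ManifestRow
from .exceptions import ConfigError
from .patch_pipeline import Patch

__all__ = [
    "PairSample",
    "SplitPlan",
    "DEFAULT_BATCH_SIZE",
    "split_by_individual",
    "make_pairs",
    "batches",
]

DEFAULT_BATCH_SIZE = 16


@dataclass(frozen=True)
class PairSample:
    """Two same-type patches plus the binary same-individual label."""

    patch_a: Patch
    patch_b: Patch
    label: int

    def __post_init__(self) -> None:
        if self.patch_a.patch_type != self.patch_b.patch_type:
            raise ConfigError(
                f"patch types differ: {self.patch_a.patch_type} vs {self.patch_b.patch_type}"
            )
        if self.label not in (0, 1):
            raise ConfigError(f"label must be 0 or 1, got {self.label}")
        same = self.patch_a.shark_id == self.patch_b.shark_id
        if self.label == 1:
            if not same:
                raise ConfigError("label=1 requires equal shark_ids")
            if self.patch_a.source_image_id == self.patch_b.source_image_id:
                raise ConfigError("label=1 requires two distinct source images")
        elif same:
            raise ConfigError("label=0 requires different shark_ids")

    @property
    def patch_type(self) -> str:
        return self.patch_a.patch_type


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test shark-id sets with per-stage train counts."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    n_train_per_stage: dict[str, int]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ConfigError(f"train/test overlap: {sorted(overlap)}")


def split_by_individual(
    rows: Sequence[ManifestRow],
    n_train: Mapping[str, int] | Sequence[int],
    seed: int,
) -> SplitPlan:
    """Randomly hold out whole individuals per life stage.

    ``n_train`` is either a mapping ``{stage: count}`` or an (adults,
    juveniles, neonates) triple. All ids not selected for training are test
    ids, so test individuals are never seen during training.
    """
    if not isinstance(n_train, Mapping):
        a, j, n = n_train
        n_train = {"adult": a, "juvenile": j, "neonate": n}
    stage_of: dict[str, str] = {}
    for row in rows:
        prev = stage_of.setdefault(row.shark_id, row.life_stage)
        if prev != row.life_stage:
            raise ConfigError(f"shark {row.shark_id} has inconsistent life stages")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for stage in LIFE_STAGES:
        ids = sorted(sid for sid, st in stage_of.items() if st == stage)
        want = int(n_train.get(stage, 0))
        if want < 0:
            raise ConfigError(f"negative train count for stage {stage}")
        if want > len(ids):
            raise ConfigError(
                f"stage {stage!r} has {len(ids)} individuals, cannot train on {want}"
            )
        chosen = sorted(rng.choice(ids, size=want, replace=False).tolist()) if want else []
        train.extend(chosen)
        test.extend(sid for sid in ids if sid not in chosen)
    return SplitPlan(
        train_ids=tuple(train),
        test_ids=tuple(test),
        n_train_per_stage={s: int(n_train.get(s, 0)) for s in LIFE_STAGES},
    )


def _positive_candidates(by_shark: Mapping[str, Sequence[Patch]]) -> list[tuple[Patch, Patch]]:
    out = []
    for sid in sorted(by_shark):
        patches = by_shark[sid]
        for i in range(len(patches)):
            for k in range(i + 1, len(patches)):
                if patches[i].source_image_id != patches[k].source_image_id:
                    out.append((patches[i], patches[k]))
    return out


def _negative_candidates(by_shark: Mapping[str, Sequence[Patch]]) -> list[tuple[Patch, Patch]]:
    sids = sorted(by_shark)
    out = []
    for i in range(len(sids)):
        for k in range(i + 1, len(sids)):
            for pa in by_shark[sids[i]]:
                for pb in by_shark[sids[k]]:
                    out.append((pa, pb))
    return out


def make_pairs(
    by_shark: Mapping[str, Sequence[Patch]],
    n_pairs: int | None = None,
    positive_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[PairSample]:
    """Sample labelled same/different patch pairs.

    All patches must share one patch type. With ``n_pairs=None`` the full
    (exhaustive) set of unordered positive and negative pairs is returned.
    Otherwise ``round(n_pairs * positive_fraction)`` positives are sampled
    without replacement (raising if that many distinct pairs do not exist)
    and negatives fill the remainder, with replacement only if the distinct
    cross-shark pairs run out.
    """
    types = {p.patch_type for ps in by_shark.values() for p in ps}
    if len(types) > 1:
        raise ConfigError(f"pairs must share one patch type, got {sorted(types)}")
    if len([s for s, ps in by_shark.items() if ps]) < 2:
        raise ConfigError("need at least two sharks with patches")
    pos_cand = _positive_candidates(by_shark)
    neg_cand = _negative_candidates(by_shark)

    if n_pairs is None:
        pairs = [PairSample(a, b, 1) for a, b in pos_cand]
        pairs += [PairSample(a, b, 0) for a, b in neg_cand]
        return pairs

    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= positive_fraction <= 1.0:
        raise ConfigError("positive_fraction must be in [0, 1]")
    n_pos = round(n_pairs * positive_fraction)
    n_neg = n_pairs - n_pos
    if n_pos > len(pos_cand):
        raise ConfigError(
            f"requested {n_pos} positive pairs but only {len(pos_cand)} distinct "
            f"positive pairs exist"
        )
    pos_idx = rng.choice(len(pos_cand), size=n_pos, replace=False) if n_pos else []
    if n_neg <= len(neg_cand):
        neg_idx = rng.choice(len(neg_cand), size=n_neg, replace=False) if n_neg else []
    else:
        neg_idx = rng.choice(len(neg_cand), size=n_neg, replace=True)
    pairs = [PairSample(*pos_cand[i], 1) for i in pos_idx]
    pairs += [PairSample(*neg_cand[i], 0) for i in neg_idx]
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def batches(
    pairs: Sequence[PairSample],
    batch_size: int = DEFAULT_BATCH_SIZE,
    rng: np.random.Generator | None = None,
) -> Iterator[list[PairSample]]:
    """One epoch of randomly permuted consecutive batches."""
    if batch_size < 1:
        raise ConfigError("batch_size must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    order = rng.permutation(len(pairs))
    for start in range(0, len(pairs), batch_size):
        yield [pairs[i] for i in order[start : start + batch_size]]
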