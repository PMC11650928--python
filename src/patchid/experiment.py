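"""End-to-end experiment orchestration from a single flat configuration.

Pipeline: simulate -> clean -> extract patches -> split by individual ->
pair generation (+ augmentation) -> train the four patch heads -> fit the
boosted fusion -> image-based and shark-based evaluation per life stage ->
temporal stability analysis. One master seed deterministically derives every
stage seed, so a rerun with the same config reproduces all reports exactly.

The default profile is the desk-scale "tiny" configuration: the seeded
random frozen test backbone (64-pixel inputs) on a synthetic population of
8 adults / 4 juveniles / 5 neonates with stage drift rates 0 / 0.02 / 0.08,
trained on 6/3/4 individuals and evaluated on everything held out.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from PIL import Image

from . import annotations_io as aio
from .annotations_io import LIFE_STAGES, PATCH_TYPES, ManifestRow
from .backbones import TinyConvBackbone
from .ensemble_fusion import EnsembleModel, FusionParams, final_similarity, fit_ensemble
from .evaluation_temporal import EvaluationReport, report_from_scores
from .exceptions import ConfigError, PatchidError
from .pairs_and_splits import PairSample, SplitPlan, split_by_individual
from .patch_pipeline import AugmentParams, Patch, apply_mask, augment, extract_patch, preprocess_for_backbone
from .similarity_net import PatchModel, embed, init_head, save_model, train_head
from .synthetic_sharks import make_population, write_dataset

__all__ = ["RunConfig", "validate_config", "run_experiment", "ExperimentResult"]


@dataclass(frozen=True)
class RunConfig:
    """Flat experiment configuration; round-trips losslessly through YAML."""

    seed: int = 7
    out_dir: str = "runs/exp"

    # synthetic population
    n_adults: int = 8
    n_juveniles: int = 4
    n_neonates: int = 5
    baseline_replicates: int = 6
    time_steps: int = 4
    time_replicates: int = 3
    image_height: int = 256
    image_width: int = 256
    body_length: float = 180.0
    drift_adult: float = 0.0
    drift_juvenile: float = 0.02
    drift_neonate: float = 0.08
    drift_steps_per_marker: int = 2

    # cleaning
    clean_min_side: int = 128
    clean_blur_threshold: float = 0.1

    # patches and backbone
    patch_size: int = 64
    backbone: str = "tiny"
    backbone_seed: int = 0

    # split and pairs
    train_adults: int = 6
    train_juveniles: int = 3
    train_neonates: int = 4
    holdout_baseline: int = 2
    n_pairs: int = 4000
    positive_fraction: float = 0.5

    # augmentation (photometric by default; geometric off for the tiny profile)
    augment_enabled: bool = True
    aug_flip_prob: float = 0.0
    aug_rot90: bool = False
    aug_noise_max: float = 8.0
    aug_blur_max: float = 1.0
    aug_gamma_lo: float = 0.8
    aug_gamma_hi: float = 1.25
    aug_contrast_lo: float = 0.85
    aug_contrast_hi: float = 1.15

    # head training
    epochs: int = 100
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    batch_size: int = 16

    # fusion
    fusion_max_trees: int = 200
    fusion_max_depth: int = 3
    fusion_learning_rate: float = 0.1
    fusion_early_stopping: int = 10
    fusion_validation_fraction: float = 0.2

    def augment_params(self) -> AugmentParams:
        return AugmentParams(
            flip_x_prob=self.aug_flip_prob,
            flip_y_prob=self.aug_flip_prob,
            rotations=(0, 90, 180, 270) if self.aug_rot90 else (0,),
            noise_max=self.aug_noise_max,
            blur_max=self.aug_blur_max,
            gamma_range=(self.aug_gamma_lo, self.aug_gamma_hi),
            contrast_range=(self.aug_contrast_lo, self.aug_contrast_hi),
        )

    def fusion_params(self) -> FusionParams:
        return FusionParams(
            max_trees=self.fusion_max_trees,
            max_depth=self.fusion_max_depth,
            learning_rate=self.fusion_learning_rate,
            validation_fraction=self.fusion_validation_fraction,
            early_stopping_rounds=self.fusion_early_stopping,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Return every invariant violation (empty list means valid)."""
    v: list[str] = []
    counts = {
        "adult": config.n_adults,
        "juvenile": config.n_juveniles,
        "neonate": config.n_neonates,
    }
    trains = {
        "adult": config.train_adults,
        "juvenile": config.train_juveniles,
        "neonate": config.train_neonates,
    }
    for stage in LIFE_STAGES:
        if counts[stage] < 0:
            v.append(f"stage {stage}: negative population count {counts[stage]}")
        if trains[stage] < 0:
            v.append(f"stage {stage}: negative train count {trains[stage]}")
        elif trains[stage] > counts[stage]:
            v.append(
                f"stage {stage}: train count {trains[stage]} exceeds population {counts[stage]}"
            )
    for name in ("drift_adult", "drift_juvenile", "drift_neonate"):
        if getattr(config, name) < 0:
            v.append(f"{name} must be >= 0")
    if config.baseline_replicates < 1:
        v.append("baseline_replicates must be >= 1")
    if config.drift_steps_per_marker < 1:
        v.append("drift_steps_per_marker must be >= 1")
    if config.time_replicates < 1:
        v.append("time_replicates must be >= 1")
    if not 0 <= config.holdout_baseline < config.baseline_replicates:
        v.append("holdout_baseline must be in [0, baseline_replicates)")
    if config.baseline_replicates - config.holdout_baseline < 2:
        v.append("need at least two non-held-out baseline replicates to form positive pairs")
    if config.image_height < 128 or config.image_width < 128:
        v.append("image size must be at least 128x128")
    if config.patch_size < 1:
        v.append("patch_size must be positive")
    if config.backbone not in ("tiny", "efficientnet-b4"):
        v.append(f"unknown backbone {config.backbone!r}")
    if config.optimizer not in ("sgd", "adam"):
        v.append(f"unknown optimizer {config.optimizer!r}")
    if config.epochs < 1:
        v.append("epochs must be >= 1")
    if config.n_pairs < 2:
        v.append("n_pairs must be >= 2")
    if not 0.0 < config.positive_fraction < 1.0:
        v.append("positive_fraction must be in (0, 1)")
    if not 0.0 < config.fusion_validation_fraction < 1.0:
        v.append("fusion_validation_fraction must be in (0, 1)")
    return v


@dataclass
class ImageRecord:
    """One manifest row with its four standardized patches."""

    row: ManifestRow
    patches: dict[str, Patch]

    @property
    def image_id(self) -> str:
        return self.row.image_id


@dataclass
class ExperimentResult:
    config: RunConfig
    population: list
    split: SplitPlan
    patch_models: dict[str, PatchModel]
    ensemble: EnsembleModel
    loss_histories: dict[str, list[float]]
    #: reports[stage][mode][model]; stage in ("all",) + LIFE_STAGES,
    #: mode in ("image", "shark"), model in PATCH_TYPES + ("fused",)
    reports: dict[str, dict[str, dict[str, EvaluationReport]]]
    #: temporal[shark_id] = {"life_stage": ..., "curve": [(marker, value)...],
    #: "verdict": "stable" | "unstable"}
    temporal: dict[str, dict]
    out_dir: Path


def _sub_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n, dtype=np.uint32)]


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageFailure):
                raise _StageFailure(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageFailure(PatchidError):
    pass


def _load_records(
    rows: Sequence[ManifestRow], root: Path, patch_size: int
) -> list[ImageRecord]:
    records = []
    for row in rows:
        with Image.open(root / row.image_path) as im:
            image = np.asarray(im.convert("RGB"))
        with Image.open(root / row.mask_path) as im:
            mask = np.asarray(im.convert("L"))
        boxes = aio.read_rolabelimg(root / row.annotation_path)
        masked = apply_mask(image, mask)
        patches = {
            b.patch_type: extract_patch(
                masked,
                b,
                out_size=patch_size,
                source_image_id=row.image_id,
                shark_id=row.shark_id,
                time_marker=row.time_marker,
            )
            for b in boxes
        }
        records.append(ImageRecord(row=row, patches=patches))
    return records


def _expand_pairs(
    base_pos: list[tuple[str, str]],
    base_neg: list[tuple[str, str]],
    n_pairs: int,
    positive_fraction: float,
    rng: np.random.Generator,
) -> list[tuple[str, str, int]]:
    """Sample (image_id_a, image_id_b, label) training instances.

    Base pairs are reused with replacement once the distinct pool is
    exhausted; augmentation later makes repeated instances distinct.
    """
    n_pos = round(n_pairs * positive_fraction)
    n_neg = n_pairs - n_pos
    out: list[tuple[str, str, int]] = []
    for cands, want, label in ((base_pos, n_pos, 1), (base_neg, n_neg, 0)):
        if not cands and want:
            raise ConfigError("no candidate pairs available for label %d" % label)
        if want <= len(cands):
            idx = rng.choice(len(cands), size=want, replace=False)
        else:
            idx = np.concatenate(
                [np.arange(len(cands)), rng.choice(len(cands), size=want - len(cands), replace=True)]
            )
        out.extend((cands[i][0], cands[i][1], label) for i in idx)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Execute the full pipeline and write every intermediate artifact."""
    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid config: " + "; ".join(violations))
    if config.backbone != "tiny":
        raise ConfigError(
            "only the 'tiny' random-frozen backbone can run without pretrained weights"
        )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (
        pop_seed,
        data_seed,
        split_seed,
        pairs_seed,
        fusion_seed,
        th_seed,
        tp_seed,
        tf_seed,
        tb_seed,
    ) = _sub_seeds(config.seed, 9)
    train_seeds = {"head": th_seed, "pec": tp_seed, "FDF": tf_seed, "FDB": tb_seed}

    with _stage("simulate"):
        population = make_population(
            config.n_adults,
            config.n_juveniles,
            config.n_neonates,
            seed=pop_seed,
            body_length=config.body_length,
        )
        drift = {
            "adult": config.drift_adult,
            "juvenile": config.drift_juvenile,
            "neonate": config.drift_neonate,
        }
        population = [replace(s, drift_rate=drift[s.life_stage]) for s in population]
        data_dir = out / "data"
        manifest_path = write_dataset(
            population,
            baseline_replicates=config.baseline_replicates,
            time_steps=config.time_steps,
            out_dir=data_dir,
            seed=data_seed,
            image_size=(config.image_height, config.image_width),
            steps_per_marker=config.drift_steps_per_marker,
            time_replicates=config.time_replicates,
        )

    with _stage("clean"):
        rows = aio.read_manifest(manifest_path)
        kept, rejections = aio.clean_dataset(
            rows,
            min_side=config.clean_min_side,
            blur_threshold=config.clean_blur_threshold,
            root=data_dir,
        )
        (out / "cleaning.json").write_text(
            json.dumps(
                {
                    "kept": len(kept),
                    "rejected": [
                        {"image": r.row.image_path, "reason": r.reason} for r in rejections
                    ],
                },
                indent=2,
            )
        )

    with _stage("prepare"):
        records = _load_records(kept, data_dir, config.patch_size)
        by_id = {r.image_id: r for r in records}

    with _stage("split"):
        split = split_by_individual(
            kept,
            (config.train_adults, config.train_juveniles, config.train_neonates),
            seed=split_seed,
        )
        with open(out / "split.csv", "w") as fh:
            fh.write("shark_id,role\n")
            for sid in split.train_ids:
                fh.write(f"{sid},train\n")
            for sid in split.test_ids:
                fh.write(f"{sid},test\n")

    # partition images: training pool = baseline images of training sharks
    # minus the held-out replicates; everything else (held-out replicates,
    # all images of test sharks, all time-series images) is test-only.
    train_pool: dict[str, list[ImageRecord]] = {}
    test_records: list[ImageRecord] = []
    baseline_by_shark: dict[str, list[ImageRecord]] = {}
    for rec in records:
        if rec.row.series == "baseline":
            baseline_by_shark.setdefault(rec.row.shark_id, []).append(rec)
    for sid in baseline_by_shark:
        baseline_by_shark[sid].sort(key=lambda r: r.image_id)
    for rec in sorted(records, key=lambda r: r.image_id):
        sid = rec.row.shark_id
        if (
            sid in split.train_ids
            and rec.row.series == "baseline"
            and config.holdout_baseline > 0
            and rec not in baseline_by_shark[sid][-config.holdout_baseline :]
        ):
            train_pool.setdefault(sid, []).append(rec)
        elif sid in split.train_ids and rec.row.series == "baseline" and config.holdout_baseline == 0:
            train_pool.setdefault(sid, []).append(rec)
        else:
            test_records.append(rec)

    with _stage("pairs"):
        rng_pairs = np.random.default_rng(pairs_seed)
        base_pos: list[tuple[str, str]] = []
        for sid in sorted(train_pool):
            imgs = [r.image_id for r in train_pool[sid]]
            base_pos.extend(
                (imgs[i], imgs[k]) for i in range(len(imgs)) for k in range(i + 1, len(imgs))
            )
        sids = sorted(train_pool)
        base_neg: list[tuple[str, str]] = []
        for i in range(len(sids)):
            for k in range(i + 1, len(sids)):
                for ra in train_pool[sids[i]]:
                    for rb in train_pool[sids[k]]:
                        base_neg.append((ra.image_id, rb.image_id))
        instances = _expand_pairs(
            base_pos, base_neg, config.n_pairs, config.positive_fraction, rng_pairs
        )
        aug_params = config.augment_params()

        def _instance_patch(image_id: str, ptype: str, rng: np.random.Generator) -> Patch:
            patch = by_id[image_id].patches[ptype]
            if config.augment_enabled:
                patch = augment(patch, aug_params, rng)
            return patch

        train_pairs: dict[str, list[PairSample]] = {t: [] for t in PATCH_TYPES}
        for ida, idb, label in instances:
            for ptype in PATCH_TYPES:
                pa = _instance_patch(ida, ptype, rng_pairs)
                pb = _instance_patch(idb, ptype, rng_pairs)
                train_pairs[ptype].append(PairSample(pa, pb, label))

    with _stage("train"):
        backbone = TinyConvBackbone(seed=config.backbone_seed)
        patch_models: dict[str, PatchModel] = {}
        loss_histories: dict[str, list[float]] = {}
        for ptype in PATCH_TYPES:
            rng_t = np.random.default_rng(train_seeds[ptype])
            model = PatchModel(
                patch_type=ptype,
                backbone=backbone,
                head=init_head(backbone.spec.feature_dim, rng_t),
            )
            model, history = train_head(
                model,
                train_pairs[ptype],
                epochs=config.epochs,
                learning_rate=config.learning_rate,
                rng=rng_t,
                batch_size=config.batch_size,
                optimizer=config.optimizer,
            )
            patch_models[ptype] = model
            loss_histories[ptype] = history
            save_model(model, out / "models" / ptype)

    with _stage("fuse"):
        # fusion is trained on the same training instances, scored without
        # augmentation (inference never augments)
        X_rows = []
        y_rows = []
        emb_train = _embedding_table(patch_models, {r.image_id: r for sid in train_pool for r in train_pool[sid]})
        for ida, idb, label in instances:
            X_rows.append(_pair_index_vector(patch_models, emb_train, ida, idb))
            y_rows.append(label)
        ensemble = fit_ensemble(
            np.asarray(X_rows),
            np.asarray(y_rows),
            params=config.fusion_params(),
            rng=np.random.default_rng(fusion_seed),
        )

    with _stage("eval"):
        reports, temporal = _evaluate(
            config, patch_models, ensemble, records, test_records, split
        )
        _write_reports(out, reports, temporal)

    config.to_yaml(out / "config.yaml")
    return ExperimentResult(
        config=config,
        population=population,
        split=split,
        patch_models=patch_models,
        ensemble=ensemble,
        loss_histories=loss_histories,
        reports=reports,
        temporal=temporal,
        out_dir=out,
    )


# ---------------------------------------------------------------------------
# vectorized evaluation internals
# ---------------------------------------------------------------------------


def _embedding_table(
    patch_models: Mapping[str, PatchModel], records_by_id: Mapping[str, ImageRecord]
) -> dict[str, dict[str, np.ndarray]]:
    """emb[ptype][image_id] = pooled embedding, computed in one batch per type."""
    ids = sorted(records_by_id)
    table: dict[str, dict[str, np.ndarray]] = {}
    for ptype, model in patch_models.items():
        spec = model.backbone.spec
        stack = np.stack(
            [
                preprocess_for_backbone(records_by_id[i].patches[ptype], spec)
                for i in ids
            ]
        )
        pooled = embed(model, stack)
        table[ptype] = {i: e for i, e in zip(ids, pooled)}
    return table


def _pair_index_vector(
    patch_models: Mapping[str, PatchModel],
    emb: Mapping[str, Mapping[str, np.ndarray]],
    ida: str,
    idb: str,
) -> np.ndarray:
    X = np.empty(len(PATCH_TYPES))
    for k, ptype in enumerate(PATCH_TYPES):
        z = np.concatenate([emb[ptype][ida], emb[ptype][idb]])[None, :]
        X[k] = patch_models[ptype].head.forward(z)[0]
    return X


def _evaluate(
    config: RunConfig,
    patch_models: Mapping[str, PatchModel],
    ensemble: EnsembleModel,
    all_records: Sequence[ImageRecord],
    test_records: Sequence[ImageRecord],
    split: SplitPlan,
):
    by_id = {r.image_id: r for r in all_records}
    emb = _embedding_table(patch_models, by_id)

    # stage evaluation uses held-out BASELINE images only: the time series
    # is reserved for the temporal analysis, so the per-stage reports measure
    # same-day distinguishability, not pattern drift
    test_by_shark: dict[str, list[str]] = {}
    stage_of: dict[str, str] = {}
    for rec in sorted(test_records, key=lambda r: r.image_id):
        stage_of[rec.row.shark_id] = rec.row.life_stage
        if rec.row.series == "baseline":
            test_by_shark.setdefault(rec.row.shark_id, []).append(rec.image_id)

    # enumerate every ordered image-id pair any report needs
    needed: dict[tuple[str, str], int] = {}

    def _need(ida: str, idb: str) -> None:
        needed.setdefault((ida, idb), len(needed))

    stages = ("all",) + LIFE_STAGES
    image_pairs: dict[str, list[tuple[str, str, int]]] = {s: [] for s in stages}
    shark_instances: dict[str, list[tuple[list[tuple[str, str]], int]]] = {s: [] for s in stages}

    def _stage_sharks(stage: str) -> list[str]:
        if stage == "all":
            return sorted(test_by_shark)
        return sorted(s for s in test_by_shark if stage_of[s] == stage)

    for stage in stages:
        sharks = _stage_sharks(stage)
        for i, sa in enumerate(sharks):
            imgs_a = test_by_shark[sa]
            for x in range(len(imgs_a)):
                for z in range(x + 1, len(imgs_a)):
                    _need(imgs_a[x], imgs_a[z])
                    image_pairs[stage].append((imgs_a[x], imgs_a[z], 1))
            for sb in sharks[i + 1 :]:
                for ida in imgs_a:
                    for idb in test_by_shark[sb]:
                        _need(ida, idb)
                        image_pairs[stage].append((ida, idb, 0))
        # shark-based instances: one baseline group per shark; cross-shark
        # group pairs are negatives, and each group with >= 2 images yields a
        # halved-group same-shark positive
        for i, sa in enumerate(sharks):
            for sb in sharks[i + 1 :]:
                cross = [
                    (ida, idb)
                    for ida in test_by_shark[sa]
                    for idb in test_by_shark[sb]
                ]
                for p in cross:
                    _need(*p)
                shark_instances[stage].append((cross, 0))
        for sa in sharks:
            imgs = test_by_shark[sa]
            if len(imgs) >= 2:
                half = len(imgs) // 2
                cross = [(a, b) for a in imgs[:half] for b in imgs[half:]]
                for p in cross:
                    _need(*p)
                shark_instances[stage].append((cross, 1))

    # temporal: every shark with time images, each marker vs its full baseline
    temporal_plan: dict[str, dict[str, list[tuple[str, str]]]] = {}
    baseline_ids: dict[str, list[str]] = {}
    time_ids: dict[str, dict[str, list[str]]] = {}
    for rec in sorted(all_records, key=lambda r: r.image_id):
        if rec.row.series == "baseline":
            baseline_ids.setdefault(rec.row.shark_id, []).append(rec.image_id)
        else:
            time_ids.setdefault(rec.row.shark_id, {}).setdefault(
                rec.row.time_marker, []
            ).append(rec.image_id)
    for sid, markers in time_ids.items():
        if sid not in baseline_ids:
            continue
        plan: dict[str, list[tuple[str, str]]] = {}
        for marker, ids in markers.items():
            plan[marker] = [(ida, idb) for ida in ids for idb in baseline_ids[sid]]
            for p in plan[marker]:
                _need(*p)
        temporal_plan[sid] = plan

    # batch-score every needed pair once per patch model
    pair_list = [None] * len(needed)
    for p, idx in needed.items():
        pair_list[idx] = p
    S = np.empty((len(pair_list), len(PATCH_TYPES)))
    for k, ptype in enumerate(PATCH_TYPES):
        E = emb[ptype]
        Z = np.stack([np.concatenate([E[a], E[b]]) for a, b in pair_list])
        S[:, k] = patch_models[ptype].head.forward(Z)
    fused = np.asarray(final_similarity(ensemble, S))
    row_of = needed

    reports: dict[str, dict[str, dict[str, EvaluationReport]]] = {}
    model_names = PATCH_TYPES + ("fused",)
    for stage in stages:
        reports[stage] = {"image": {}, "shark": {}}
        ipairs = image_pairs[stage]
        if ipairs:
            rows = [row_of[(a, b)] for a, b, _ in ipairs]
            labels = [lab for _, _, lab in ipairs]
            for k, name in enumerate(model_names):
                scores = (S[rows, k] if name != "fused" else fused[rows]).tolist()
                reports[stage]["image"][name] = report_from_scores(scores, list(labels))
        ginst = shark_instances[stage]
        if ginst:
            labels = [lab for _, lab in ginst]
            for k, name in enumerate(model_names):
                scores = []
                for cross, _lab in ginst:
                    rows = [row_of[p] for p in cross]
                    vals = S[rows, k] if name != "fused" else fused[rows]
                    scores.append(float(np.mean(vals)))
                reports[stage]["shark"][name] = report_from_scores(scores, list(labels))

    temporal: dict[str, dict] = {}
    for sid, plan in temporal_plan.items():
        curve = []
        for marker in sorted(plan, key=aio.parse_time_marker):
            rows = [row_of[p] for p in plan[marker]]
            curve.append((marker, float(np.mean(fused[rows]))))
        temporal[sid] = {
            "life_stage": stage_of.get(sid) or _stage_from_records(all_records, sid),
            "curve": curve,
            "verdict": "stable" if all(v > 0.5 for _, v in curve) else "unstable",
        }
    return reports, temporal


def _stage_from_records(records: Sequence[ImageRecord], sid: str) -> str:
    for r in records:
        if r.row.shark_id == sid:
            return r.row.life_stage
    raise ConfigError(f"unknown shark {sid}")


def _write_reports(out: Path, reports, temporal) -> None:
    rep_dir = out / "reports"
    rep_dir.mkdir(parents=True, exist_ok=True)
    serial = {
        stage: {
            mode: {name: rep.to_dict() for name, rep in per_mode.items()}
            for mode, per_mode in per_stage.items()
        }
        for stage, per_stage in reports.items()
    }
    (rep_dir / "evaluation.json").write_text(json.dumps(serial, indent=2, sort_keys=True))
    (rep_dir / "temporal.json").write_text(json.dumps(temporal, indent=2, sort_keys=True))
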