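"""Synthetic spot-pattern dataset generator.

Produces labelled populations of synthetic sharks: each individual carries a
unique spot pattern painted on a capsule-shaped dorsal silhouette with a dark
ocellus landmark behind the pectoral region. Same-day baseline replicates vary
only in photographic nuisance (in-plane view angle, gamma, blur, noise), while
time-series renders advance an ontogenetic drift process whose strength
depends on life stage: adult patterns are exactly stable, juvenile patterns
drift slowly and neonate patterns drift strongly.

Drift law (one time step): every spot center takes an isotropic Gaussian step
with per-axis standard deviation ``drift_rate * body_length``, and each spot
independently dies with probability ``drift_rate``, immediately replaced by a
newborn spot at a fresh uniform location. The walk is reproducible from
``(base_seed, t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .annotations_io import (
    LIFE_STAGES,
    PATCH_TYPES,
    ManifestRow,
    RotatedBox,
    write_manifest,
    write_rolabelimg,
)
from .exceptions import ConfigError, RenderError

__all__ = [
    "DRIFT_RATE_DEFAULTS",
    "IndividualSpec",
    "RenderConfig",
    "SpotSet",
    "RenderedSample",
    "make_population",
    "drift_pattern",
    "render",
    "write_dataset",
]

#: Default per-time-step drift rates by life stage.
DRIFT_RATE_DEFAULTS = {"adult": 0.0, "juvenile": 0.02, "neonate": 0.08}

#: Per-stage pattern design: (n_spots, radius divisors, layout, jitter/L).
STAGE_PATTERN = {
    "adult": (28, (38.0, 24.0), "uniform", 0.0),
    "juvenile": (36, (48.0, 30.0), "lattice", 0.015),
    "neonate": (60, (60.0, 40.0), "lattice", 0.0003),
}

#: Capsule half-width as a fraction of body length.
BODY_HALF_WIDTH_FRAC = 0.14

#: Body-relative patch-box geometry: (center x/L, center y/L, w/L, h/L).
#: The body x-axis points toward the head (head at +x).
BOX_LAYOUT = {
    "head": (0.36, 0.0, 0.20, 0.20),
    "pec": (0.15, 0.0, 0.18, 0.24),
    "FDF": (-0.10, 0.0, 0.18, 0.24),
    "FDB": (-0.32, 0.0, 0.18, 0.24),
}

#: Ocellus landmark: (center x/L, center y/L, radius/L).
OCELLUS = (0.10, 0.08, 0.045)

_SKIN_RGB = np.array([182.0, 152.0, 112.0])
_SPOT_RGB = np.array([42.0, 32.0, 24.0])
_BACKGROUNDS = ("plain", "gravel", "sand")


@dataclass(frozen=True)
class IndividualSpec:
    """One synthetic shark: identity seed, life stage and drift parameters."""

    shark_id: str
    life_stage: str
    base_seed: int
    n_spots: int = 28
    spot_radius_range: tuple[float, float] = (4.0, 7.0)
    body_length: float = 180.0
    drift_rate: float = 0.0
    #: "uniform": fully individual spot layout; "lattice": stage-common base
    #: layout plus per-individual Gaussian jitter of sd jitter_frac * length
    layout: str = "uniform"
    jitter_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise ConfigError(f"unknown life stage {self.life_stage!r}")
        if self.n_spots < 1:
            raise ConfigError("n_spots must be >= 1")
        if self.drift_rate < 0:
            raise ConfigError("drift_rate must be >= 0")
        lo, hi = self.spot_radius_range
        if not (0 < lo <= hi):
            raise ConfigError("spot_radius_range must satisfy 0 < lo <= hi")
        if self.layout not in ("uniform", "lattice"):
            raise ConfigError(f"unknown layout {self.layout!r}")
        if self.jitter_frac < 0:
            raise ConfigError("jitter_frac must be >= 0")


@dataclass(frozen=True)
class RenderConfig:
    """Photographic nuisance parameters for one render."""

    image_size: tuple[int, int] = (256, 256)  # (H, W)
    view_angle: float = 0.0  # degrees, in-plane body rotation
    gamma: float = 1.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    background: str = "plain"
    render_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 128 or w < 128:
            raise ConfigError(f"image size must be at least 128x128, got {self.image_size}")
        if self.gamma <= 0:
            raise ConfigError("gamma must be > 0")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ConfigError("blur_sigma and noise_sd must be >= 0")
        if self.background not in _BACKGROUNDS:
            raise ConfigError(f"unknown background {self.background!r}")


@dataclass(frozen=True)
class SpotSet:
    """A spot pattern in body coordinates (origin at body center, x toward head)."""

    ids: np.ndarray  # (n,) int64, stable across drift while a spot survives
    xy: np.ndarray  # (n, 2) float64
    radii: np.ndarray  # (n,) float64

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class RenderedSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8, 0 background / 255 shark
    boxes: tuple[RotatedBox, ...]
    shark_id: str
    series: str = "baseline"
    time_marker: str = ""


def make_population(
    n_adults: int,
    n_juveniles: int,
    n_neonates: int,
    seed: int,
    body_length: float = 180.0,
) -> list[IndividualSpec]:
    """Create a seeded population of unique individuals."""
    for name, n in (("n_adults", n_adults), ("n_juveniles", n_juveniles), ("n_neonates", n_neonates)):
        if n < 0:
            raise ConfigError(f"{name} must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    specs: list[IndividualSpec] = []
    idx = 0
    # Identity is carried by spot LAYOUT, never by gross statistics: counts
    # are fixed per stage so texture cues that survive drift stay
    # uninformative. Immature stages share a stage-common lattice layout and
    # differ only by a small per-individual jitter of many fine markings:
    # littermates genuinely look alike, and one drift step displaces a spot
    # by several jitter scales, erasing individual correspondence. An adult
    # (drift 0) keeps its fully individual coarse layout forever.
    for stage, count in (("adult", n_adults), ("juvenile", n_juveniles), ("neonate", n_neonates)):
        n_spots, (lo_div, hi_div), layout, jitter = STAGE_PATTERN[stage]
        for _ in range(count):
            base_seed = int(rng.integers(0, 2**31 - 1))
            specs.append(
                IndividualSpec(
                    shark_id=f"HO_{100 + idx}",
                    life_stage=stage,
                    base_seed=base_seed,
                    n_spots=n_spots,
                    spot_radius_range=(body_length / lo_div, body_length / hi_div),
                    body_length=body_length,
                    drift_rate=DRIFT_RATE_DEFAULTS[stage],
                    layout=layout,
                    jitter_frac=jitter,
                )
            )
            idx += 1
    return specs


def _capsule_inside(x: np.ndarray, y: np.ndarray, length: float, half_width: float) -> np.ndarray:
    """Signed membership of points in a capsule along the x-axis."""
    rect_half = length / 2.0 - half_width
    dx = np.maximum(np.abs(x) - rect_half, 0.0)
    return np.hypot(dx, y) <= half_width


def _sample_spots_uniform(rng: np.random.Generator, n: int, spec: IndividualSpec) -> np.ndarray:
    """Rejection-sample n spot centers uniformly inside the body capsule."""
    L = spec.body_length
    hw = BODY_HALF_WIDTH_FRAC * L
    # keep spot centers a radius away from the rim so spots read as interior
    margin = spec.spot_radius_range[1]
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform(
            low=(-L / 2.0, -hw), high=(L / 2.0, hw), size=(max(4 * (n - got), 16), 2)
        )
        ok = _capsule_inside(cand[:, 0], cand[:, 1], L - 2 * margin, hw - margin)
        cand = cand[ok]
        take = min(len(cand), n - got)
        out[got : got + take] = cand[:take]
        got += take
    return out


#: seed of the stage-common lattice layout (shared by every individual)
_LATTICE_SEED = 715517


def _base_spots(spec: IndividualSpec) -> SpotSet:
    rng = np.random.default_rng(spec.base_seed)
    lo, hi = spec.spot_radius_range
    if spec.layout == "lattice":
        # base positions AND radii come from the stage-common generator:
        # the per-spot radius multiset must not be an individual fingerprint
        # (it survives drift, unlike the jittered positions)
        common = np.random.default_rng(_LATTICE_SEED)
        xy = _sample_spots_uniform(common, spec.n_spots, spec)
        radii = common.uniform(lo, hi, size=spec.n_spots)
        xy = xy + rng.normal(0.0, spec.jitter_frac * spec.body_length, size=xy.shape)
    else:
        xy = _sample_spots_uniform(rng, spec.n_spots, spec)
        radii = rng.uniform(lo, hi, size=spec.n_spots)
    return SpotSet(ids=np.arange(spec.n_spots, dtype=np.int64), xy=xy, radii=radii)


def drift_pattern(spec: IndividualSpec, t: int) -> SpotSet:
    """Spot pattern of ``spec`` after ``t`` drift steps; reproducible."""
    if t < 0:
        raise ConfigError("t must be >= 0")
    spots = _base_spots(spec)
    if spec.drift_rate == 0.0 or t == 0:
        return spots
    next_id = spec.n_spots
    ids, xy, radii = spots.ids.copy(), spots.xy.copy(), spots.radii.copy()
    sigma = spec.drift_rate * spec.body_length
    lo, hi = spec.spot_radius_range
    for step in range(1, t + 1):
        rng = np.random.default_rng(np.random.SeedSequence((spec.base_seed, step)))
        xy = xy + rng.normal(0.0, sigma, size=xy.shape)
        dead = rng.random(len(ids)) < spec.drift_rate
        n_dead = int(dead.sum())
        if n_dead:
            xy[dead] = _sample_spots_uniform(rng, n_dead, spec)
            radii[dead] = rng.uniform(lo, hi, size=n_dead)
            ids[dead] = np.arange(next_id, next_id + n_dead)
            next_id += n_dead
    return SpotSet(ids=ids, xy=xy, radii=radii)


def _rotation(deg: float) -> np.ndarray:
    """Clockwise-positive in-plane rotation matrix in pixel coordinates."""
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


def render(spec: IndividualSpec, t: int, cfg: RenderConfig) -> RenderedSample:
    """Render one photograph-like sample with mask and the four patch boxes."""
    H, W = cfg.image_size
    L = spec.body_length
    hw = BODY_HALF_WIDTH_FRAC * L
    if L / 2.0 + 2.0 > min(H, W) / 2.0:
        raise RenderError(
            f"body of length {L} does not fit in a {H}x{W} image under rotation"
        )

    center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    R = _rotation(cfg.view_angle)
    # body coords of every pixel center: b = R^-1 (p - center)
    ys, xs = np.mgrid[0:H, 0:W]
    px = xs - center[0]
    py = ys - center[1]
    bx = R[0, 0] * px + R[1, 0] * py
    by = R[0, 1] * px + R[1, 1] * py

    inside = _capsule_inside(bx, by, L, hw)
    mask = np.where(inside, 255, 0).astype(np.uint8)

    rng = np.random.default_rng(cfg.render_seed)

    # background layer
    img = np.empty((H, W, 3), dtype=np.float64)
    if cfg.background == "plain":
        img[:] = 24.0
    else:
        base = 60.0 if cfg.background == "gravel" else 96.0
        tex = rng.normal(0.0, 14.0, size=(H, W))
        tex = gaussian_filter(tex, 1.5 if cfg.background == "gravel" else 3.0)
        img[:] = (base + tex)[..., None]

    # skin with a gentle lengthwise shading gradient
    shade = 1.0 - 0.12 * (bx / (L / 2.0))
    skin = _SKIN_RGB[None, None, :] * shade[..., None]
    img = np.where(inside[..., None], skin, img)

    # spots (painted only inside the silhouette), antialiased at the rim
    spots = drift_pattern(spec, t)
    spot_cov = np.zeros((H, W))
    for (sx, sy), r in zip(spots.xy, spots.radii):
        d = np.hypot(bx - sx, by - sy)
        spot_cov = np.maximum(spot_cov, np.clip(r + 0.5 - d, 0.0, 1.0))
    # ocellus landmark: dark disc with a pale ring, a fixed anatomical anchor
    ox, oy, orad = OCELLUS
    d = np.hypot(bx - ox * L, by - oy * L)
    ring = np.clip(orad * L * 1.45 + 0.5 - d, 0.0, 1.0)
    disc = np.clip(orad * L + 0.5 - d, 0.0, 1.0)
    img = np.where(inside[..., None], img * (1 - ring[..., None]) + 230.0 * ring[..., None], img)
    dark = np.maximum(spot_cov, disc) * inside
    img = img * (1 - dark[..., None]) + _SPOT_RGB[None, None, :] * dark[..., None]

    # photographic nuisance: gamma, blur, additive noise
    if cfg.gamma != 1.0:
        img = np.clip(img, 0.0, 255.0)
        img = 255.0 * (img / 255.0) ** cfg.gamma
    if cfg.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0.0))
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    boxes = []
    angle = math.radians(cfg.view_angle % 360.0)
    for ptype in PATCH_TYPES:
        fx, fy, fw, fh = BOX_LAYOUT[ptype]
        c = R @ np.array([fx * L, fy * L]) + center
        boxes.append(
            RotatedBox(patch_type=ptype, cx=float(c[0]), cy=float(c[1]),
                       w=fw * L, h=fh * L, angle=angle)
        )
    return RenderedSample(image=img, mask=mask, boxes=tuple(boxes), shark_id=spec.shark_id)


@dataclass(frozen=True)
class NuisanceRanges:
    """Sampling ranges for per-photo nuisance in write_dataset.

    ``annotation_sd`` / ``annotation_angle_sd`` model hand-labelling error:
    the boxes written to disk are Gaussian-perturbed around their true
    body-relative placement, as a human annotator's would be.
    """

    view_angle: tuple[float, float] = (-12.0, 12.0)
    gamma: tuple[float, float] = (0.85, 1.2)
    blur_sigma: tuple[float, float] = (0.0, 0.6)
    noise_sd: tuple[float, float] = (0.0, 5.0)
    annotation_sd: float = 0.5  # pixels, box-center jitter
    annotation_angle_sd: float = 0.015  # radians


def sample_render_config(
    rng: np.random.Generator,
    image_size: tuple[int, int] = (256, 256),
    ranges: NuisanceRanges = NuisanceRanges(),
    background: str = "plain",
) -> RenderConfig:
    return RenderConfig(
        image_size=image_size,
        view_angle=float(rng.uniform(*ranges.view_angle)),
        gamma=float(rng.uniform(*ranges.gamma)),
        blur_sigma=float(rng.uniform(*ranges.blur_sigma)),
        noise_sd=float(rng.uniform(*ranges.noise_sd)),
        background=background,
        render_seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_dataset(
    population: Sequence[IndividualSpec],
    baseline_replicates: int,
    time_steps: int,
    out_dir: str | Path,
    seed: int,
    image_size: tuple[int, int] = (256, 256),
    nuisance: NuisanceRanges = NuisanceRanges(),
    steps_per_marker: int = 1,
    time_replicates: int = 1,
) -> Path:
    """Render and write a full dataset; returns the manifest path.

    Baseline replicates of one shark share t=0 (same-day photographs, no
    drift between them) and differ only in nuisance. Time-series images
    carry markers T0..T(time_steps-1) with the drift process advanced to
    t = k * steps_per_marker.
    """
    if baseline_replicates < 1:
        raise ConfigError("baseline_replicates must be >= 1")
    if steps_per_marker < 1:
        raise ConfigError("steps_per_marker must be >= 1")
    if time_replicates < 1:
        raise ConfigError("time_replicates must be >= 1")
    out = Path(out_dir)
    for sub in ("images", "masks", "annotations"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    rows: list[ManifestRow] = []
    # baseline photographs all share the undrifted t=0 state (same-day:
    # no morphological change among them)
    baseline_t = 0
    for spec in population:
        renders: list[tuple[str, str, str, int]] = []  # (stem, series, marker, t)
        for rep in range(baseline_replicates):
            renders.append((f"{spec.shark_id}_B0P{rep}", "baseline", "", baseline_t))
        for k in range(time_steps):
            for r in range(time_replicates):
                stem = (
                    f"{spec.shark_id}_T{k}"
                    if time_replicates == 1
                    else f"{spec.shark_id}_T{k}P{r}"
                )
                renders.append((stem, "time", f"T{k}", k * steps_per_marker))
        for stem, series, marker, t in renders:
            cfg = sample_render_config(rng, image_size=image_size, ranges=nuisance)
            sample = render(spec, t, cfg)
            image_path = f"images/{stem}.png"
            mask_path = f"masks/{stem}.png"
            ann_path = f"annotations/{stem}.xml"
            Image.fromarray(sample.image).save(out / image_path)
            Image.fromarray(sample.mask).save(out / mask_path)
            boxes = [
                replace(
                    b,
                    cx=b.cx + rng.normal(0.0, nuisance.annotation_sd),
                    cy=b.cy + rng.normal(0.0, nuisance.annotation_sd),
                    angle=b.angle + rng.normal(0.0, nuisance.annotation_angle_sd),
                )
                for b in sample.boxes
            ]
            write_rolabelimg(boxes, image_path, out / ann_path)
            rows.append(
                ManifestRow(
                    image_path=image_path,
                    mask_path=mask_path,
                    annotation_path=ann_path,
                    shark_id=spec.shark_id,
                    life_stage=spec.life_stage,
                    series=series,
                    time_marker=marker,
                )
            )
    manifest_path = out / "manifest.csv"
    write_manifest(rows, manifest_path)
    return manifest_path
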