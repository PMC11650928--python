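"""On-disk artifact I/O: rotated-box annotation XML, manifests, dataset cleaning.

Annotations use the roLabelImg dialect: an ``annotation`` root containing one
``object`` node per labelled region, each with a ``robndbox`` child holding
``cx, cy, w, h, angle``. Coordinates are 0-based pixel-center coordinates
(x rightward, y downward); ``angle`` is in radians, clockwise positive in
pixel coordinates, normalized into [0, 2*pi).
"""

from __future__ import annotations

import csv
import hashlib
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .exceptions import FormatError

__all__ = [
    "PATCH_TYPES",
    "LIFE_STAGES",
    "RotatedBox",
    "ManifestRow",
    "MANIFEST_FIELDS",
    "read_rolabelimg",
    "write_rolabelimg",
    "read_manifest",
    "write_manifest",
    "clean_dataset",
    "laplacian_variance",
]

#: Canonical patch label order used everywhere downstream.
PATCH_TYPES = ("head", "pec", "FDF", "FDB")

LIFE_STAGES = ("neonate", "juvenile", "adult")

MANIFEST_FIELDS = (
    "image_path",
    "mask_path",
    "annotation_path",
    "shark_id",
    "life_stage",
    "series",
    "time_marker",
)

_TIME_MARKER_RE = re.compile(r"^T(\d+)$")
TWO_PI = 2.0 * math.pi


def normalize_angle(angle: float) -> float:
    """Map an angle in radians into [0, 2*pi)."""
    a = math.fmod(float(angle), TWO_PI)
    if a < 0:
        a += TWO_PI
    if a >= TWO_PI:  # fmod rounding at the boundary
        a -= TWO_PI
    return a


@dataclass(frozen=True)
class RotatedBox:
    """One labelled skin patch as a rotated rectangle.

    The box's own x-axis points toward the animal's head; ``w`` is the extent
    along that axis and ``h`` the perpendicular extent.
    """

    patch_type: str
    cx: float
    cy: float
    w: float
    h: float
    angle: float

    def __post_init__(self) -> None:
        if self.patch_type not in PATCH_TYPES:
            raise FormatError(
                f"unrecognized patch label {self.patch_type!r}; "
                f"expected one of {PATCH_TYPES}"
            )
        if not (self.w > 0 and self.h > 0):
            raise FormatError(f"box extents must be positive, got w={self.w}, h={self.h}")
        object.__setattr__(self, "angle", normalize_angle(self.angle))


def parse_time_marker(marker: str) -> int:
    """Return the numeric index of a time marker like ``T3``."""
    m = _TIME_MARKER_RE.match(marker)
    if m is None:
        raise FormatError(f"bad time marker {marker!r}; expected T<non-negative integer>")
    return int(m.group(1))


@dataclass(frozen=True)
class ManifestRow:
    image_path: str
    mask_path: str
    annotation_path: str
    shark_id: str
    life_stage: str
    series: str
    time_marker: str = ""
    #: upstream curation flag (e.g. non-dorsal orientation); not serialized
    exclude: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise FormatError(f"unknown life stage {self.life_stage!r}")
        if self.series == "time":
            parse_time_marker(self.time_marker)
        elif self.series == "baseline":
            if self.time_marker:
                raise FormatError(
                    f"baseline row for {self.shark_id!r} must have an empty "
                    f"time marker, got {self.time_marker!r}"
                )
        else:
            raise FormatError(f"unknown series {self.series!r}")

    @property
    def image_id(self) -> str:
        return Path(self.image_path).stem

    @property
    def time_index(self) -> int | None:
        if self.series != "time":
            return None
        return parse_time_marker(self.time_marker)


# ---------------------------------------------------------------------------
# roLabelImg XML
# ---------------------------------------------------------------------------

_ROBNDBOX_FIELDS = ("cx", "cy", "w", "h", "angle")


def read_rolabelimg(xml_path: str | Path) -> list[RotatedBox]:
    """Parse a roLabelImg annotation file into a list of RotatedBox."""
    try:
        tree = ET.parse(str(xml_path))
    except ET.ParseError as exc:
        raise FormatError(f"{xml_path}: not parseable as XML: {exc}") from exc
    root = tree.getroot()
    boxes: list[RotatedBox] = []
    seen: set[str] = set()
    for obj in root.iter("object"):
        name_el = obj.find("name")
        if name_el is None or not (name_el.text or "").strip():
            raise FormatError(f"{xml_path}: <object> without a <name>")
        name = name_el.text.strip()
        if name not in PATCH_TYPES:
            raise FormatError(
                f"{xml_path}: unrecognized patch label {name!r}; "
                f"expected one of {PATCH_TYPES}"
            )
        if name in seen:
            raise FormatError(f"{xml_path}: duplicate patch label {name!r}")
        seen.add(name)
        rb = obj.find("robndbox")
        if rb is None:
            raise FormatError(f"{xml_path}: object {name!r} has no <robndbox>")
        values = {}
        for fld in _ROBNDBOX_FIELDS:
            el = rb.find(fld)
            if el is None or el.text is None:
                raise FormatError(f"{xml_path}: object {name!r} missing robndbox field {fld!r}")
            values[fld] = float(el.text)
        boxes.append(RotatedBox(patch_type=name, **values))
    return boxes


def write_rolabelimg(
    boxes: Sequence[RotatedBox], image_path: str | Path, xml_path: str | Path
) -> None:
    """Write exactly one box per patch type to a roLabelImg-dialect file."""
    types = [b.patch_type for b in boxes]
    dupes = sorted({t for t in types if types.count(t) > 1})
    if dupes:
        raise FormatError(f"duplicate patch types in box list: {dupes}")
    by_type = {b.patch_type: b for b in boxes}
    missing = [t for t in PATCH_TYPES if t not in by_type]
    if missing:
        raise FormatError(f"missing patch types: {missing}")

    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = Path(image_path).name
    ET.SubElement(root, "path").text = str(image_path)
    for t in PATCH_TYPES:
        b = by_type[t]
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.patch_type
        ET.SubElement(obj, "type").text = "robndbox"
        rb = ET.SubElement(obj, "robndbox")
        for fld in _ROBNDBOX_FIELDS:
            ET.SubElement(rb, fld).text = repr(float(getattr(b, fld)))
    ET.indent(root)
    ET.ElementTree(root).write(str(xml_path), encoding="unicode")


# ---------------------------------------------------------------------------
# Manifest CSV
# ---------------------------------------------------------------------------


def write_manifest(rows: Iterable[ManifestRow], csv_path: str | Path) -> None:
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_FIELDS)
        for row in rows:
            writer.writerow([getattr(row, f) for f in MANIFEST_FIELDS])


def read_manifest(csv_path: str | Path) -> list[ManifestRow]:
    rows: list[ManifestRow] = []
    with open(csv_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != MANIFEST_FIELDS:
            raise FormatError(
                f"{csv_path}: bad manifest header {header!r}; expected {list(MANIFEST_FIELDS)}"
            )
        for i, rec in enumerate(reader, start=2):
            if len(rec) != len(MANIFEST_FIELDS):
                raise FormatError(f"{csv_path}:{i}: expected {len(MANIFEST_FIELDS)} fields")
            try:
                rows.append(ManifestRow(**dict(zip(MANIFEST_FIELDS, rec))))
            except FormatError as exc:
                raise FormatError(f"{csv_path}:{i}: {exc}") from exc
    return rows


# ---------------------------------------------------------------------------
# Dataset cleaning
# ---------------------------------------------------------------------------


def laplacian_variance(gray: np.ndarray) -> float:
    """Variance-of-Laplacian sharpness score of a 2-D intensity array."""
    from scipy.ndimage import laplace

    return float(np.var(laplace(np.asarray(gray, dtype=np.float64))))


@dataclass(frozen=True)
class Rejection:
    row: ManifestRow
    reason: str


def clean_dataset(
    rows: Sequence[ManifestRow],
    min_side: int = 380,
    blur_threshold: float = 1.0,
    root: str | Path | None = None,
) -> tuple[list[ManifestRow], list[Rejection]]:
    """Remove duplicates, tiny, blurry, unreadable and flagged images.

    Duplicates are byte-identical files (first occurrence kept). ``root``, if
    given, is prepended to relative manifest paths.
    """
    kept: list[ManifestRow] = []
    rejected: list[Rejection] = []
    seen_hashes: set[str] = set()
    base = Path(root) if root is not None else Path(".")
    for row in rows:
        if row.exclude:
            rejected.append(Rejection(row, "excluded"))
            continue
        path = Path(row.image_path)
        if not path.is_absolute():
            path = base / path
        try:
            data = path.read_bytes()
            with Image.open(path) as im:
                arr = np.asarray(im.convert("L"), dtype=np.float64)
        except (OSError, ValueError):
            rejected.append(Rejection(row, "unreadable"))
            continue
        digest = hashlib.sha256(data).hexdigest()
        if digest in seen_hashes:
            rejected.append(Rejection(row, "duplicate"))
            continue
        if min(arr.shape) < min_side:
            seen_hashes.add(digest)
            rejected.append(Rejection(row, f"low-resolution (shorter side {min(arr.shape)} < {min_side})"))
            continue
        if laplacian_variance(arr) < blur_threshold:
            seen_hashes.add(digest)
            rejected.append(Rejection(row, "blurry"))
            continue
        seen_hashes.add(digest)
        kept.append(row)
    return kept, rejected
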