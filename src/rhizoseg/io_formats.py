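"""Annotation and mask I/O for minirhizotron root images.

Masks are binary rasters (0 = soil background, 1 = root) stored as
indexed-colour PNGs with the palette background -> (0,0,0) and
root -> (128,0,0), the convention used by minirhizotron annotation
pipelines built on labelme. Polygon annotations come in as labelme JSON;
rasterization uses a pixel-centre containment rule (a pixel belongs to a
polygon iff its centre at integer+0.5 coordinates lies inside it).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

#: Fixed mask palette: class index -> RGB.
MASK_PALETTE = ((0, 0, 0), (128, 0, 0))


class FormatError(ValueError):
    """Raised when a document does not conform to the expected schema."""


class UnsupportedShapeError(FormatError):
    """Raised for annotation shape types that cannot map to a binary mask."""


class LabelingError(ValueError):
    """Raised when a shape label has no class mapping and is not ignored."""


@dataclass
class LabelMask:
    """Per-pixel class indices (0 = background, 1 = root)."""

    data: np.ndarray
    num_classes: int = 2

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.data.shape}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.num_classes):
            raise ValueError(
                f"mask values must lie in [0, {self.num_classes}); "
                f"got range [{self.data.min()}, {self.data.max()}]"
            )
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self):
        return self.data.shape

    def foreground_fraction(self) -> float:
        return float((self.data != 0).mean())

    def __eq__(self, other):
        return (
            isinstance(other, LabelMask)
            and self.num_classes == other.num_classes
            and self.data.shape == other.data.shape
            and bool((self.data == other.data).all())
        )


@dataclass
class ImageSample:
    """An RGB image with its ground-truth mask."""

    image: np.ndarray
    mask: LabelMask
    identifier: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got {self.image.shape}")
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} differ in size"
            )


@dataclass
class PolygonAnnotation:
    """Labelme-style polygon annotation for one image."""

    shapes: list  # list of (label: str, points: (n, 2) float array)
    image_height: int
    image_width: int

    def __post_init__(self):
        clipped = []
        for label, points in self.shapes:
            pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
            if len(pts) < 3:
                raise FormatError(f"polygon {label!r} has {len(pts)} < 3 points")
            pts[:, 0] = np.clip(pts[:, 0], 0.0, self.image_width)
            pts[:, 1] = np.clip(pts[:, 1], 0.0, self.image_height)
            clipped.append((label, pts))
        self.shapes = clipped


def read_labelme(source) -> PolygonAnnotation:
    """Read a labelme JSON document (path, file object, or parsed dict).

    Polygon shapes pass through untouched; rectangle shapes (two corner
    points) expand to the 4-corner polygon. Other shape types raise
    :class:`UnsupportedShapeError`.
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        doc = json.loads(Path(source).read_text())

    for key in ("shapes", "imageHeight", "imageWidth"):
        if key not in doc:
            raise FormatError(f"labelme document is missing required key {key!r}")

    shapes = []
    for shape in doc["shapes"]:
        stype = shape.get("shape_type", "polygon")
        label = shape.get("label", "")
        points = np.asarray(shape.get("points", []), dtype=np.float64)
        if stype == "polygon":
            shapes.append((label, points))
        elif stype == "rectangle":
            if points.shape != (2, 2):
                raise FormatError(
                    f"rectangle {label!r} needs exactly 2 corner points, got {points.shape}"
                )
            (x0, y0), (x1, y1) = points
            shapes.append(
                (label, np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]))
            )
        else:
            raise UnsupportedShapeError(
                f"shape type {stype!r} (label {label!r}) cannot map to a binary mask"
            )
    return PolygonAnnotation(
        shapes=shapes,
        image_height=int(doc["imageHeight"]),
        image_width=int(doc["imageWidth"]),
    )


def rasterize(
    annotation: PolygonAnnotation,
    label_map: dict | None = None,
    ignore_unknown: bool = False,
    num_classes: int = 2,
) -> LabelMask:
    """Paint polygons onto a class-index raster.

    A pixel gets a polygon's class iff its centre (column+0.5, row+0.5) is
    inside the polygon; later shapes overwrite earlier ones.
    """
    if label_map is None:
        label_map = {"root": 1}
    h, w = annotation.image_height, annotation.image_width
    out = np.zeros((h, w), dtype=np.uint8)
    if annotation.shapes:
        yy, xx = np.mgrid[0:h, 0:w]
        centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
        for label, pts in annotation.shapes:
            if label not in label_map:
                if ignore_unknown:
                    continue
                raise LabelingError(
                    f"label {label!r} has no class mapping and ignore_unknown is off"
                )
            inside = MplPath(pts).contains_points(centers).reshape(h, w)
            out[inside] = label_map[label]
    return LabelMask(out, num_classes=num_classes)


def write_mask_png(mask: LabelMask, path) -> None:
    """Write a mask as an indexed-colour PNG with the fixed root palette."""
    if mask.num_classes > len(MASK_PALETTE):
        raise ValueError(
            f"num_classes={mask.num_classes} exceeds palette size {len(MASK_PALETTE)}"
        )
    img = Image.fromarray(mask.data, mode="P")
    palette = list(sum(MASK_PALETTE, ())) + [0] * (768 - 3 * len(MASK_PALETTE))
    img.putpalette(palette)
    img.save(path, format="PNG")


def read_mask_png(path) -> LabelMask:
    """Read a palette-PNG mask; recover from RGB or wrong-palette files.

    Non-indexed input (or an indexed file with a different palette) is
    mapped to the nearest palette colour with a warning.
    """
    img = Image.open(path)
    if img.mode == "P":
        data = np.asarray(img, dtype=np.uint8)
        pal = img.getpalette() or []
        n = len(MASK_PALETTE)
        if tuple(pal[: 3 * n]) == tuple(sum(MASK_PALETTE, ())) and (
            data.max(initial=0) < n
        ):
            return LabelMask(data, num_classes=n)
        warnings.warn(f"{path}: unexpected palette; recovering by nearest colour")
        rgb = np.asarray(img.convert("RGB"), dtype=np.int32)
    else:
        warnings.warn(f"{path}: mask is not an indexed PNG; recovering by nearest colour")
        rgb = np.asarray(img.convert("RGB"), dtype=np.int32)
    colors = np.asarray(MASK_PALETTE, dtype=np.int32)  # (K, 3)
    dist = ((rgb[:, :, None, :] - colors[None, None, :, :]) ** 2).sum(axis=-1)
    return LabelMask(dist.argmin(axis=-1).astype(np.uint8), num_classes=len(MASK_PALETTE))


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)


def split_dataset(identifiers, ratios=(8, 1, 1), seed: int = 0):
    """Deterministic train/val/test split by largest-remainder apportionment.

    Ratios are normalized to 1; sizes are the largest-remainder apportionment
    of ``n * ratio`` so the partition is exact and reproducible.
    """
    identifiers = list(identifiers)
    n = len(identifiers)
    if n == 0:
        raise ValueError("cannot split an empty identifier list")
    ratios = np.asarray(ratios, dtype=float)
    if (ratios <= 0).any():
        raise ValueError(f"ratios must be positive, got {tuple(ratios)}")
    ratios = ratios / ratios.sum()

    quotas = n * ratios
    sizes = np.floor(quotas).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(quotas - sizes), kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1

    if (sizes == 0).any():
        warnings.warn(
            f"split of {n} items at ratios {tuple(round(float(r), 4) for r in ratios)} "
            f"leaves an empty partition (sizes {tuple(int(s) for s in sizes)})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [identifiers[i] for i in perm]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0] : sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1] :]
    return train, val, test


def write_split_manifests(splits, out_dir) -> None:
    """Write one plain-text manifest per partition (one identifier per line)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, ids in zip(("train", "val", "test"), splits):
        (out_dir / f"{name}.txt").write_text("".join(i + "\n" for i in ids))


def read_split_manifest(path) -> list:
    return [line for line in Path(path).read_text().splitlines() if line]


def load_dataset_dir(root) -> list:
    """Load image/mask pairs from the images/ + masks/ directory layout."""
    root = Path(root)
    samples = []
    for img_path in sorted((root / "images").iterdir()):
        ident = img_path.stem
        mask_path = root / "masks" / f"{ident}.png"
        samples.append(
            ImageSample(
                image=read_image(img_path),
                mask=read_mask_png(mask_path),
                identifier=ident,
            )
        )
    return samples
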