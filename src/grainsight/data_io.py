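"""Images, bounding-box annotations, and Pascal-VOC (labelImg dialect) I/O.

Internal coordinate convention: 0-based, half-open ``[xmin, xmax) x [ymin, ymax)``
with the origin at the image's top-left corner, so ``width = xmax - xmin`` exactly.
VOC XML files store 1-based *inclusive* pixel indices (the convention written by
labelImg); the converters below translate between the two losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from lxml import etree
from PIL import Image

__all__ = [
    "BoundingBox",
    "Annotation",
    "ImageRecord",
    "VocParseError",
    "VocConsistencyError",
    "read_voc_xml",
    "write_voc_xml",
    "crop_to_tiles",
    "augment_record",
    "AUGMENT_OPS",
    "read_manifest",
    "write_manifest",
]


class VocParseError(ValueError):
    """An expected element is missing or malformed in a VOC XML file."""


class VocConsistencyError(ValueError):
    """XML metadata disagrees with the image it annotates."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        coords = (self.xmin, self.ymin, self.xmax, self.ymax)
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"non-finite box coordinates {coords}")
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"degenerate box {coords}: requires xmax>xmin, ymax>ymin")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def to_array(self) -> np.ndarray:
        return np.array([self.xmin, self.ymin, self.xmax, self.ymax], dtype=np.float64)

    @staticmethod
    def from_array(a) -> "BoundingBox":
        x0, y0, x1, y1 = (float(v) for v in a)
        return BoundingBox(x0, y0, x1, y1)


@dataclass(frozen=True)
class Annotation:
    label: str
    box: BoundingBox
    difficult: bool = False


@dataclass
class ImageRecord:
    """An image plus its ground-truth annotations.

    ``pixels`` is ``uint8 (height, width, 3)`` or ``None`` when only geometry is
    needed (e.g. pure annotation transforms).
    """

    image_id: str
    width: int
    height: int
    pixels: np.ndarray | None = None
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixels is not None:
            h, w = self.pixels.shape[:2]
            if (w, h) != (self.width, self.height):
                raise ValueError(
                    f"pixel array {w}x{h} does not match declared size "
                    f"{self.width}x{self.height}"
                )
        for ann in self.annotations:
            if not ann.difficult:
                b = ann.box
                if b.xmin < 0 or b.ymin < 0 or b.xmax > self.width or b.ymax > self.height:
                    raise ValueError(
                        f"non-difficult annotation {b} outside image "
                        f"{self.width}x{self.height}"
                    )

    def gt_boxes(self, include_difficult: bool = False) -> np.ndarray:
        """(N, 4) float array of annotation boxes."""
        anns = [a for a in self.annotations if include_difficult or not a.difficult]
        if not anns:
            return np.zeros((0, 4), dtype=np.float64)
        return np.stack([a.box.to_array() for a in anns])


# ---------------------------------------------------------------------------
# VOC XML
# ---------------------------------------------------------------------------

def _req(parent, tag: str):
    el = parent.find(tag)
    if el is None:
        raise VocParseError(f"missing element <{tag}> under <{parent.tag}>")
    return el


def _req_number(parent, tag: str) -> float:
    el = _req(parent, tag)
    try:
        return float(el.text)
    except (TypeError, ValueError) as exc:
        raise VocParseError(f"element <{tag}> is not numeric: {el.text!r}") from exc


def read_voc_xml(xml_path, image_path=None) -> ImageRecord:
    """Read a labelImg/Pascal-VOC annotation file (optionally with its image).

    VOC 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention: ``xmin -> xmin - 1``, ``ymin -> ymin - 1``; xmax/ymax
    are unchanged.
    """
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as exc:
        raise VocParseError(f"ill-formed XML in {xml_path}: {exc}") from exc
    root = tree.getroot()

    size = _req(root, "size")
    width = int(_req_number(size, "width"))
    height = int(_req_number(size, "height"))

    pixels = None
    if image_path is not None:
        with Image.open(image_path) as im:
            pixels = np.asarray(im.convert("RGB"))
        ih, iw = pixels.shape[:2]
        if (iw, ih) != (width, height):
            raise VocConsistencyError(
                f"image {image_path} is {iw}x{ih} but XML declares {width}x{height}"
            )

    annotations: list[Annotation] = []
    for obj in root.findall("object"):
        label_el = _req(obj, "name")
        if not label_el.text:
            raise VocParseError("empty <name> in <object>")
        diff_el = obj.find("difficult")
        difficult = bool(int(diff_el.text)) if diff_el is not None and diff_el.text else False
        bnd = _req(obj, "bndbox")
        xmin = _req_number(bnd, "xmin") - 1.0
        ymin = _req_number(bnd, "ymin") - 1.0
        xmax = _req_number(bnd, "xmax")
        ymax = _req_number(bnd, "ymax")
        annotations.append(Annotation(label_el.text, BoundingBox(xmin, ymin, xmax, ymax), difficult))

    image_id = root.findtext("filename") or xml_path.stem
    image_id = Path(image_id).stem
    return ImageRecord(image_id, width, height, pixels, annotations)


def _fmt_coord(v: float) -> str:
    # labelImg writes integers; keep that when exact, otherwise preserve the float
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_voc_xml(record: ImageRecord, xml_path, image_filename: str | None = None) -> Path:
    """Write a labelImg-compatible XML file (inverse of :func:`read_voc_xml`)."""
    for ann in record.annotations:
        b = ann.box
        if b.xmin < 0 or b.ymin < 0 or b.xmax > record.width or b.ymax > record.height:
            raise ValueError(f"refusing to write annotation outside image: {b}")

    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = image_filename or f"{record.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(record.width)
    etree.SubElement(size, "height").text = str(record.height)
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for ann in record.annotations:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = ann.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "1" if ann.difficult else "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = _fmt_coord(ann.box.xmin + 1.0)
        etree.SubElement(bnd, "ymin").text = _fmt_coord(ann.box.ymin + 1.0)
        etree.SubElement(bnd, "xmax").text = _fmt_coord(ann.box.xmax)
        etree.SubElement(bnd, "ymax").text = _fmt_coord(ann.box.ymax)

    xml_path = Path(xml_path)
    xml_path.write_bytes(etree.tostring(root, pretty_print=True))
    return xml_path


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def _tile_origins(extent: int, tile: int) -> list[int]:
    origins = list(range(0, extent - tile + 1, tile))
    if origins[-1] != extent - tile:
        origins.append(extent - tile)
    return origins


def crop_to_tiles(
    record: ImageRecord,
    tile_w: int = 640,
    tile_h: int = 480,
    min_box_retention: float = 0.5,
) -> list[ImageRecord]:
    """Tile a large frame into ``tile_w x tile_h`` crops.

    Tiles are laid on a grid from the top-left; the final row/column is shifted
    inward so no tile exceeds the image (adjacent tiles may overlap). Annotations
    are clipped to each tile and dropped when the clipped box retains less than
    ``min_box_retention`` of its original area.
    """
    if tile_w > record.width or tile_h > record.height:
        raise ValueError(
            f"tile {tile_w}x{tile_h} larger than image {record.width}x{record.height}"
        )
    if tile_w == record.width and tile_h == record.height:
        return [record]

    tiles: list[ImageRecord] = []
    for oy in _tile_origins(record.height, tile_h):
        for ox in _tile_origins(record.width, tile_w):
            anns: list[Annotation] = []
            for ann in record.annotations:
                b = ann.box
                x0 = max(b.xmin, ox)
                y0 = max(b.ymin, oy)
                x1 = min(b.xmax, ox + tile_w)
                y1 = min(b.ymax, oy + tile_h)
                if x1 <= x0 or y1 <= y0:
                    continue
                if (x1 - x0) * (y1 - y0) < min_box_retention * b.area:
                    continue
                anns.append(
                    replace(ann, box=BoundingBox(x0 - ox, y0 - oy, x1 - ox, y1 - oy))
                )
            pixels = None
            if record.pixels is not None:
                pixels = record.pixels[oy : oy + tile_h, ox : ox + tile_w].copy()
            tiles.append(
                ImageRecord(
                    f"{record.image_id}_x{ox}_y{oy}", tile_w, tile_h, pixels, anns
                )
            )
    return tiles


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

AUGMENT_OPS = ("rot+90", "rot-90", "hflip", "vflip")


def _transform_box(box: BoundingBox, op: str, w: int, h: int) -> BoundingBox:
    x0, y0, x1, y1 = box.xmin, box.ymin, box.xmax, box.ymax
    if op == "hflip":
        return BoundingBox(w - x1, y0, w - x0, y1)
    if op == "vflip":
        return BoundingBox(x0, h - y1, x1, h - y0)
    if op == "rot+90":  # counter-clockwise; new frame is h x w
        return BoundingBox(y0, w - x1, y1, w - x0)
    if op == "rot-90":  # clockwise
        return BoundingBox(h - y1, x0, h - y0, x1)
    raise ValueError(f"unknown augmentation op {op!r}; expected one of {AUGMENT_OPS}")


def augment_record(record: ImageRecord, op: str) -> ImageRecord:
    """Apply one label-preserving augmentation: 90-degree rotations or flips.

    Pixels and every box are transformed consistently under the half-open
    convention; labels and difficult flags are untouched. Rotations swap the
    image's width and height.
    """
    if op not in AUGMENT_OPS:
        raise ValueError(f"unknown augmentation op {op!r}; expected one of {AUGMENT_OPS}")
    w, h = record.width, record.height
    pixels = record.pixels
    if pixels is not None:
        if op == "hflip":
            pixels = pixels[:, ::-1].copy()
        elif op == "vflip":
            pixels = pixels[::-1].copy()
        elif op == "rot+90":
            pixels = np.rot90(pixels, k=1).copy()
        else:
            pixels = np.rot90(pixels, k=3).copy()
    new_w, new_h = (h, w) if op.startswith("rot") else (w, h)
    anns = [replace(a, box=_transform_box(a.box, op, w, h)) for a in record.annotations]
    return ImageRecord(f"{record.image_id}_{op}", new_w, new_h, pixels, anns)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(pairs: Iterable[tuple[str, str]], path) -> Path:
    """Write a plain-text manifest of tab-separated (image, xml) path pairs."""
    path = Path(path)
    lines = [f"{img}\t{xml}" for img, xml in pairs]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_manifest(path) -> list[tuple[Path, Path]]:
    """Read a manifest; relative paths resolve against the manifest directory."""
    path = Path(path)
    base = path.parent
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        img, xml = line.split("\t")
        out.append((base / img, base / xml))
    return out


def load_records(manifest_path) -> list[ImageRecord]:
    """Load every (image, xml) pair of a manifest into memory."""
    return [read_voc_xml(xml, img) for img, xml in read_manifest(manifest_path)]
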