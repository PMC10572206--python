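"""Synthetic grain-surface scenes with dense, small, optionally clustered insects.

Emulates the statistics of stored-grain pest imagery so the whole detection
pipeline is testable without proprietary data: a textured background of
overlapping grain-colored ellipses under an illumination gradient, and insects
drawn as dark rotated ellipses with a class-specific pronotum patch (sharp
cornered for the "Cfb" morphotype, rounded for "Rfb") and a class-specific hue.
Laboratory-like scenes carry 1-7 insects per 640x480 frame; field-like scenes
20-50; body sizes span 8-48 px and label aspect ratios 0.3-2.2. Insects placed
as aggregates overlap heavily, which is precisely the regime score-decay
suppression (Soft-NMS) is meant to handle.

The generator is deterministic: identical (config, seed) gives bit-identical
pixels and annotations. Per-image seeds of a dataset derive from the master
seed via ``numpy.random.SeedSequence((master_seed, image_index))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from PIL import Image
from scipy import ndimage

from ._boxes import iou_matrix
from .data_io import Annotation, BoundingBox, ImageRecord, write_manifest, write_voc_xml

__all__ = [
    "SceneConfig",
    "PlacementError",
    "lab_scene_config",
    "field_scene_config",
    "small_scene_config",
    "generate_scene",
    "generate_dataset",
]


class PlacementError(RuntimeError):
    """Raised when insects cannot be placed without violating a constraint."""


@dataclass(frozen=True)
class SceneConfig:
    width: int = 640
    height: int = 480
    classes: tuple[str, ...] = ("Cfb", "Rfb")
    class_weights: tuple[float, ...] = (0.5, 0.5)
    count_range: tuple[int, int] = (1, 7)
    size_range: tuple[float, float] = (8.0, 48.0)  # sqrt(box area), px
    aspect_range: tuple[float, float] = (0.3, 2.2)  # box height / width
    cluster_prob: float = 0.3
    cluster_size_range: tuple[int, int] = (3, 5)
    grain_coverage: float = 2.0  # expected grain-ellipse area / image area
    color_jitter: float = 12.0  # uint8 units, grain and insect color spread
    illum_gradient: float = 0.15  # relative amplitude of the illumination ramp
    difficult_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (0 < lo <= hi <= min(self.width, self.height)):
            raise ValueError(f"invalid size_range {self.size_range}")
        if self.count_range[0] < 0 or self.count_range[0] > self.count_range[1]:
            raise ValueError(f"invalid count_range {self.count_range}")
        if len(self.classes) < 1 or len(self.classes) != len(self.class_weights):
            raise ValueError("classes and class_weights must align")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1")
        if self.aspect_range[0] > self.aspect_range[1]:
            raise ValueError("aspect_range lo must be <= hi")
        if not (0.0 <= self.cluster_prob <= 1.0):
            raise ValueError("cluster_prob must lie in [0, 1]")


def lab_scene_config(**overrides) -> SceneConfig:
    """Laboratory-like frames: 640x480, 1-7 insects."""
    return SceneConfig(**overrides)


def field_scene_config(**overrides) -> SceneConfig:
    """Field-like 640x480 tiles: 20-50 insects, frequent aggregation."""
    defaults = dict(count_range=(20, 50), cluster_prob=0.5)
    defaults.update(overrides)
    return SceneConfig(**defaults)


def small_scene_config(**overrides) -> SceneConfig:
    """Desk-scale 160x160 scenes used by fast end-to-end runs and examples."""
    defaults = dict(
        width=160,
        height=160,
        count_range=(3, 8),
        size_range=(10.0, 32.0),
        aspect_range=(0.5, 2.0),
        cluster_prob=0.3,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


# class-specific appearance: (body RGB, pronotum RGB, sharp_pronotum)
_CLASS_STYLE = {
    0: ((58, 50, 42), (78, 68, 56), True),  # gray-brown, sharp pronotum corners
    1: ((98, 44, 26), (128, 62, 38), False),  # reddish-brown, rounded pronotum
}
_WHEAT = np.array([186.0, 158.0, 112.0])


def _render_background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _WHEAT * rng.uniform(0.92, 1.05)

    mean_grain_area = math.pi * 8.0 * 4.5
    n_grains = int(cfg.grain_coverage * w * h / mean_grain_area)
    yy_base, xx_base = np.mgrid[0:h, 0:w]
    for _ in range(n_grains):
        a = rng.uniform(5.5, 10.5)  # semi-major, px
        b = rng.uniform(3.0, 5.5)
        th = rng.uniform(0.0, math.pi)
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        x0, x1 = int(max(0, cx - a - 1)), int(min(w, cx + a + 2))
        y0, y1 = int(max(0, cy - a - 1)), int(min(h, cy + a + 2))
        if x1 <= x0 or y1 <= y0:
            continue
        dx = xx_base[y0:y1, x0:x1] + 0.5 - cx
        dy = yy_base[y0:y1, x0:x1] + 0.5 - cy
        u = (dx * math.cos(th) + dy * math.sin(th)) / a
        v = (-dx * math.sin(th) + dy * math.cos(th)) / b
        r2 = u * u + v * v
        mask = r2 <= 1.0
        color = _WHEAT + rng.normal(0.0, cfg.color_jitter, size=3)
        shade = 1.0 - 0.25 * r2[mask]  # darker toward the kernel edge
        img[y0:y1, x0:x1][mask] = color[None, :] * shade[:, None]

    # directional illumination ramp
    phi = rng.uniform(0.0, 2.0 * math.pi)
    proj = (xx_base + 0.5 - w / 2) * math.cos(phi) + (yy_base + 0.5 - h / 2) * math.sin(phi)
    proj /= max(abs(proj.max()), abs(proj.min()), 1.0)
    img *= (1.0 + cfg.illum_gradient * proj)[:, :, None]

    img = ndimage.gaussian_filter(img, sigma=(0.8, 0.8, 0.0))
    img += rng.normal(0.0, 3.0, size=img.shape)
    return img


def _sample_insect_geometry(
    cfg: SceneConfig, rng: np.random.Generator
) -> tuple[float, float, float, float, float]:
    """Sample (A, q, theta, box_w, box_h) for one insect body ellipse.

    ``A`` is the semi-major axis, ``q = B/A`` the elongation, ``theta`` the
    orientation. The tight bounding box of the rotated ellipse is solved
    analytically and the semi-axes scaled so sqrt(box area) hits the sampled
    target size; orientations whose box aspect falls outside the configured
    range are resampled.
    """
    lo, hi = cfg.size_range
    target = rng.uniform(min(lo + 1.0, hi), max(hi - 1.0, lo))
    alo, ahi = cfg.aspect_range
    for _ in range(64):
        q = rng.uniform(0.40, 0.62)
        th = rng.uniform(0.0, math.pi)
        wx = 2.0 * math.sqrt(math.cos(th) ** 2 + q**2 * math.sin(th) ** 2)
        wy = 2.0 * math.sqrt(math.sin(th) ** 2 + q**2 * math.cos(th) ** 2)
        aspect = wy / wx
        if alo * 1.05 <= aspect <= ahi * 0.95:
            break
    else:
        th, q = math.pi / 4, 0.5
        wx = wy = 2.0 * math.sqrt(0.5 + 0.25 * 0.5)
    A = target / math.sqrt(wx * wy)
    return A, q, th, A * wx, A * wy


def _render_insect(
    img: np.ndarray,
    cfg: SceneConfig,
    rng: np.random.Generator,
    cls_idx: int,
    cx: float,
    cy: float,
    A: float,
    q: float,
    th: float,
) -> tuple[int, int, int, int] | None:
    """Draw one insect; return the rendered mask's tight pixel bounds."""
    h, w = img.shape[:2]
    B = q * A
    half_w = math.sqrt((A * math.cos(th)) ** 2 + (B * math.sin(th)) ** 2)
    half_h = math.sqrt((A * math.sin(th)) ** 2 + (B * math.cos(th)) ** 2)
    x0 = int(max(0, math.floor(cx - half_w - 1)))
    x1 = int(min(w, math.ceil(cx + half_w + 1)))
    y0 = int(max(0, math.floor(cy - half_h - 1)))
    y1 = int(min(h, math.ceil(cy + half_h + 1)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    u = dx * math.cos(th) + dy * math.sin(th)  # along major axis
    v = -dx * math.sin(th) + dy * math.cos(th)
    body = (u / A) ** 2 + (v / B) ** 2 <= 1.0
    if not body.any():
        return None

    body_rgb, pro_rgb, sharp = _CLASS_STYLE[cls_idx % 2]
    jitter = rng.normal(0.0, cfg.color_jitter * 0.4, size=3)
    color = np.clip(np.asarray(body_rgb, dtype=np.float64) + jitter, 0, 255)
    r2 = np.where(body, (u / A) ** 2 + (v / B) ** 2, 1.0)
    shade = 1.0 - 0.35 * r2
    patch = img[y0:y1, x0:x1]
    patch[body] = color[None, :] * shade[body][:, None]

    # pronotum patch on the front third; corner sharpness separates the classes
    if sharp:
        pro = body & (u >= 0.35 * A) & (u <= 0.85 * A) & (np.abs(v) <= 0.85 * B)
    else:
        pu = (u - 0.60 * A) / (0.25 * A)
        pv = v / (0.70 * B)
        pro = body & (pu * pu + pv * pv <= 1.0)
    pro_color = np.clip(np.asarray(pro_rgb, dtype=np.float64) + jitter, 0, 255)
    patch[pro] = pro_color

    rows = np.flatnonzero(body.any(axis=1))
    cols = np.flatnonzero(body.any(axis=0))
    return (x0 + cols[0], y0 + rows[0], x0 + cols[-1] + 1, y0 + rows[-1] + 1)


def generate_scene(config: SceneConfig, seed: int | None = None) -> ImageRecord:
    """Render one annotated grain scene.

    Bounding boxes are the tight pixel bounds of each rendered insect; all
    non-difficult boxes lie inside the image, sizes (sqrt of box area) fall in
    ``config.size_range`` and aspect ratios in ``config.aspect_range``. Raises
    :class:`PlacementError` when the requested count cannot be placed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    img = _render_background(config, rng)
    w, h = config.width, config.height

    count = int(rng.integers(config.count_range[0], config.count_range[1] + 1))
    annotations: list[Annotation] = []
    placed_boxes: list[np.ndarray] = []

    remaining = count
    while remaining > 0:
        clo, chi = config.cluster_size_range
        if remaining >= clo and rng.random() < config.cluster_prob:
            group = int(rng.integers(clo, min(chi, remaining) + 1))
        else:
            group = 1
        cluster_center = None
        for _ in range(group):
            ok = False
            for _attempt in range(200):
                A, q, th, bw, bh = _sample_insect_geometry(config, rng)
                if bw >= w - 2 or bh >= h - 2:
                    continue
                if cluster_center is None:
                    cx = rng.uniform(bw / 2 + 1, w - bw / 2 - 1)
                    cy = rng.uniform(bh / 2 + 1, h - bh / 2 - 1)
                else:
                    spread = 0.45 * math.sqrt(bw * bh)
                    cx = float(np.clip(cluster_center[0] + rng.normal(0, spread),
                                       bw / 2 + 1, w - bw / 2 - 1))
                    cy = float(np.clip(cluster_center[1] + rng.normal(0, spread),
                                       bh / 2 + 1, h - bh / 2 - 1))
                cand = np.array([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2])
                if group == 1 and placed_boxes:
                    if iou_matrix(cand, np.stack(placed_boxes)).max() > 0.25:
                        continue
                cls_idx = int(rng.choice(len(config.classes), p=config.class_weights))
                bounds = _render_insect(img, config, rng, cls_idx, cx, cy, A, q, th)
                if bounds is None:
                    continue
                bx0, by0, bx1, by1 = bounds
                size = math.sqrt((bx1 - bx0) * (by1 - by0))
                aspect = (by1 - by0) / (bx1 - bx0)
                if not (config.size_range[0] <= size <= config.size_range[1]):
                    continue
                if not (config.aspect_range[0] <= aspect <= config.aspect_range[1]):
                    continue
                box = BoundingBox(float(bx0), float(by0), float(bx1), float(by1))
                difficult = bool(rng.random() < config.difficult_prob)
                annotations.append(Annotation(config.classes[cls_idx], box, difficult))
                placed_boxes.append(box.to_array())
                if cluster_center is None:
                    cluster_center = (cx, cy)
                ok = True
                break
            if not ok:
                raise PlacementError(
                    f"could not place insect {len(annotations) + 1}/{count} within "
                    f"size_range={config.size_range}, aspect_range={config.aspect_range} "
                    f"inside {w}x{h} after bounded retries"
                )
            remaining -= 1

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    image_id = f"scene_{(config.seed if seed is None else seed):010d}"
    return ImageRecord(image_id, w, h, pixels, annotations)


def _image_seed(master_seed: int, index: int) -> int:
    """Documented per-image seed derivation (stable across platforms)."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def generate_records(n_images: int, config: SceneConfig) -> list[ImageRecord]:
    """Generate ``n_images`` scenes in memory (no files written)."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    records = []
    for i in range(n_images):
        rec = generate_scene(config, _image_seed(config.seed, i))
        rec.image_id = f"scene_{i:05d}"
        records.append(rec)
    return records


def generate_dataset(n_images: int, config: SceneConfig, out_dir) -> Path:
    """Write ``n_images`` PNG + VOC-XML pairs plus a manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for i, rec in enumerate(generate_records(n_images, config)):
        img_name = f"{rec.image_id}.png"
        xml_name = f"{rec.image_id}.xml"
        Image.fromarray(rec.pixels).save(out_dir / img_name)
        write_voc_xml(rec, out_dir / xml_name, image_filename=img_name)
        pairs.append((img_name, xml_name))
    return write_manifest(pairs, out_dir / "manifest.tsv")
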