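"""Dataset tooling: YOLO-segmentation polygon labels, train/val splitting,
six-transform augmentation, mosaic, and a synthetic fundus-image generator.

The synthetic generator emulates colour fundus photographs of pathological
myopia: a dark surround, a circular retinal field, an optic disc, a few
dark vessels, and 1-3 bright irregular atrophic patches (perturbed ellipses
near the disc, mimicking peripapillary atrophy).  Every lesion's exact
polygon is stored as ground truth, and the internal lesion raster is
produced from the *rounded* (6-decimal) polygon so that re-rasterising the
emitted label reproduces it pixel for pixel.

Coordinate convention: normalised to [0, 1], origin top-left, x rightward,
y downward; a pixel belongs to a polygon mask iff its centre lies inside
(even-odd rule).
"""

from __future__ import annotations

import logging
import os
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageOps

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


class LabelParseError(ValueError):
    pass


@dataclass
class InstanceAnnotation:
    class_id: int
    polygon: np.ndarray  # (k, 2) normalised vertices

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 \
                or self.polygon.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if self.polygon.min() < -1e-9 or self.polygon.max() > 1 + 1e-9:
            raise ValueError("polygon coordinates must lie in [0, 1]")

    @property
    def box(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) normalised, derived from the polygon."""
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return float(x.min()), float(y.min()), float(x.max()), float(y.max())

    def mask(self, h: int, w: int) -> np.ndarray:
        return polygon_to_mask(self.polygon, h, w)


@dataclass
class ImageSample:
    id: str
    image: np.ndarray  # (H, W, 3) uint8
    instances: list[InstanceAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be HxWx3")


@dataclass
class SynthConfig:
    n_images: int = 8
    image_size: int = 256
    lesions_per_image: tuple[int, int] = (1, 3)
    fundus_radius_fraction: float = 0.92
    lesion_intensity_range: tuple[int, int] = (180, 240)
    background_intensity_range: tuple[int, int] = (5, 25)
    n_classes: int = 1
    lesion_free_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 0:
            raise ValueError("n_images must be non-negative")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if not (0 < self.fundus_radius_fraction <= 1):
            raise ValueError("fundus_radius_fraction must be in (0, 1]")
        if self.n_classes not in (1, 2):
            raise ValueError("n_classes must be 1 or 2")


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]


@dataclass
class DatasetManifest:
    root: str
    images: list[str]
    labels: list[str]

    def save(self, path) -> None:
        # stored root is relative to the manifest so datasets are relocatable
        path = Path(path)
        try:
            rel = os.path.relpath(self.root, path.parent)
        except ValueError:  # pragma: no cover - different drives
            rel = self.root
        path.write_text(yaml.safe_dump(
            {"root": rel, "images": self.images, "labels": self.labels},
            sort_keys=False))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        d = yaml.safe_load(path.read_text())
        root = Path(d["root"])
        if not root.is_absolute():
            root = (path.parent / root).resolve()
        return cls(root=str(root), images=d["images"], labels=d["labels"])


# ---------------------------------------------------------------------------
# rasterisation


def polygon_to_mask(polygon: np.ndarray, h: int, w: int) -> np.ndarray:
    """Rasterise a normalised polygon: pixel centres inside (even-odd rule)."""
    poly = np.asarray(polygon, dtype=np.float64)
    px = poly[:, 0] * w
    py = poly[:, 1] * h
    mask = np.zeros((h, w), dtype=bool)
    x0 = max(int(np.floor(px.min())), 0)
    x1 = min(int(np.ceil(px.max())) + 1, w)
    y0 = max(int(np.floor(py.min())), 0)
    y1 = min(int(np.ceil(py.max())) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return mask
    cx = np.arange(x0, x1) + 0.5
    cy = np.arange(y0, y1) + 0.5
    gx, gy = np.meshgrid(cx, cy)
    inside = np.zeros(gx.shape, dtype=bool)
    k = len(px)
    for i in range(k):
        xi, yi = px[i], py[i]
        xj, yj = px[(i + 1) % k], py[(i + 1) % k]
        crosses = (yi > gy) != (yj > gy)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = xi + (gy - yi) * (xj - xi) / (yj - yi)
        inside ^= crosses & (gx < x_at)
    mask[y0:y1, x0:x1] = inside
    return mask


def mask_to_box(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return None
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


# ---------------------------------------------------------------------------
# label I/O (YOLO segmentation dialect)


def read_labels(path) -> list[InstanceAnnotation]:
    """Parse ``class x1 y1 ... xk yk`` lines (normalised, k >= 3)."""
    anns = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        try:
            class_id = int(parts[0])
            coords = [float(v) for v in parts[1:]]
        except ValueError as e:
            raise LabelParseError(f"{path}:{lineno}: unparseable token ({e})")
        if len(coords) % 2:
            raise LabelParseError(
                f"{path}:{lineno}: odd coordinate count {len(coords)}")
        if len(coords) < 6:
            raise LabelParseError(
                f"{path}:{lineno}: polygon needs >= 3 vertices, got {len(coords) // 2}")
        if min(coords) < 0 or max(coords) > 1:
            raise LabelParseError(
                f"{path}:{lineno}: coordinates outside [0, 1]")
        if class_id < 0:
            raise LabelParseError(f"{path}:{lineno}: negative class id")
        anns.append(InstanceAnnotation(
            class_id, np.array(coords, dtype=np.float64).reshape(-1, 2)))
    return anns


def write_labels(annotations: list[InstanceAnnotation], path) -> None:
    lines = []
    for a in annotations:
        coords = " ".join(f"{v:.6f}" for v in a.polygon.reshape(-1))
        lines.append(f"{a.class_id} {coords}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# split


def split_dataset(ids: list[str], train_fraction: float = 0.9,
                  seed: int = 0) -> DatasetSplit:
    """Deterministic shuffled split; the train share is rounded up."""
    if not ids:
        raise ValueError("ids must be non-empty")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = math.ceil(train_fraction * len(ids))
    shuffled = [ids[i] for i in order]
    return DatasetSplit(train=shuffled[:n_train], val=shuffled[n_train:])


# ---------------------------------------------------------------------------
# six-transform augmentation


def _clip_instances(instances, note: str):
    out = []
    for a in instances:
        poly = np.clip(a.polygon, 0.0, 1.0)
        x1, y1, x2, y2 = poly[:, 0].min(), poly[:, 1].min(), \
            poly[:, 0].max(), poly[:, 1].max()
        if (x2 - x1) <= 1e-9 or (y2 - y1) <= 1e-9:
            log.warning("dropping degenerate instance after %s", note)
            continue
        out.append(InstanceAnnotation(a.class_id, poly))
    return out


def _hist_equalize(sample: ImageSample) -> ImageSample:
    img = ImageOps.equalize(Image.fromarray(sample.image))
    return ImageSample(sample.id + "_histeq", np.asarray(img), sample.instances)


def _grayscale(sample: ImageSample) -> ImageSample:
    lum = (0.299 * sample.image[..., 0] + 0.587 * sample.image[..., 1]
           + 0.114 * sample.image[..., 2]).astype(np.uint8)
    return ImageSample(sample.id + "_gray",
                       np.repeat(lum[:, :, None], 3, axis=2), sample.instances)


def _linear_color(sample: ImageSample, rng: np.random.Generator) -> ImageSample:
    a = rng.uniform(0.8, 1.2, size=3)
    b = rng.uniform(-20.0, 20.0, size=3)
    img = np.clip(sample.image.astype(np.float64) * a + b, 0, 255).astype(np.uint8)
    return ImageSample(sample.id + "_lincol", img, sample.instances)


def hflip(sample: ImageSample) -> ImageSample:
    insts = [InstanceAnnotation(a.class_id,
                                np.column_stack([1.0 - a.polygon[:, 0],
                                                 a.polygon[:, 1]]))
             for a in sample.instances]
    return ImageSample(sample.id + "_hflip", sample.image[:, ::-1],
                       _clip_instances(insts, "hflip"))


def vflip(sample: ImageSample) -> ImageSample:
    insts = [InstanceAnnotation(a.class_id,
                                np.column_stack([a.polygon[:, 0],
                                                 1.0 - a.polygon[:, 1]]))
             for a in sample.instances]
    return ImageSample(sample.id + "_vflip", sample.image[::-1],
                       _clip_instances(insts, "vflip"))


def rotate90(sample: ImageSample, k: int) -> ImageSample:
    """Counter-clockwise right-angle rotation (k quarter turns); polygons
    stay exactly representable."""
    k = k % 4
    img = np.rot90(sample.image, k)
    insts = sample.instances
    for _ in range(k):
        insts = [InstanceAnnotation(a.class_id,
                                    np.column_stack([a.polygon[:, 1],
                                                     1.0 - a.polygon[:, 0]]))
                 for a in insts]
    return ImageSample(f"{sample.id}_rot{90 * k}", img,
                       _clip_instances(insts, "rotation"))


def augment_sixfold(samples: list[ImageSample], seed: int = 0
                    ) -> list[ImageSample]:
    """Original plus six variants per sample: histogram equalisation,
    grayscale, horizontal flip, linear colour, right-angle rotation,
    vertical flip.  Output count is exactly 7x the input count."""
    if not samples:
        raise ValueError("samples must be non-empty")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        out.append(s)
        out.append(_hist_equalize(s))
        out.append(_grayscale(s))
        out.append(hflip(s))
        out.append(_linear_color(s, rng))
        out.append(rotate90(s, int(rng.integers(1, 4))))
        out.append(vflip(s))
    return out


# ---------------------------------------------------------------------------
# mosaic


def mosaic_augment(samples: list[ImageSample], output_size: int,
                   seed: int = 0, center: tuple[int, int] | None = None
                   ) -> ImageSample:
    """Tile four samples around a centre point; each image is resized into
    its quadrant and polygons are remapped by the same affine transform."""
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly 4 samples")
    if output_size <= 0:
        raise ValueError("output_size must be positive")
    rng = np.random.default_rng(seed)
    s = output_size
    if center is None:
        cx = int(rng.uniform(0.25, 0.75) * s)
        cy = int(rng.uniform(0.25, 0.75) * s)
    else:
        cx, cy = center
    canvas = np.zeros((s, s, 3), dtype=np.uint8)
    quads = [(0, 0, cx, cy), (cx, 0, s - cx, cy),
             (0, cy, cx, s - cy), (cx, cy, s - cx, s - cy)]
    instances = []
    for smp, (qx, qy, qw, qh) in zip(samples, quads):
        if qw <= 0 or qh <= 0:
            continue
        tile = np.asarray(Image.fromarray(smp.image).resize(
            (qw, qh), Image.BILINEAR))
        canvas[qy:qy + qh, qx:qx + qw] = tile
        for a in smp.instances:
            poly = np.column_stack([(qx + a.polygon[:, 0] * qw) / s,
                                    (qy + a.polygon[:, 1] * qh) / s])
            instances.append(InstanceAnnotation(a.class_id, poly))
    return ImageSample("mosaic", canvas, _clip_instances(instances, "mosaic"))


# ---------------------------------------------------------------------------
# synthetic fundus generator


def _lesion_polygon(rng: np.random.Generator, cx: float, cy: float,
                    r0: float, k: int = 28) -> np.ndarray:
    """Perturbed ellipse: radius modulated by low-frequency sinusoids."""
    theta = np.linspace(0.0, 2 * np.pi, k, endpoint=False)
    ecc = rng.uniform(0.6, 1.0)
    rot = rng.uniform(0, np.pi)
    r = np.full(k, 1.0)
    for j in (2, 3, 5):
        r += rng.uniform(0.0, 0.14) * np.sin(j * theta + rng.uniform(0, 2 * np.pi))
    xs = r0 * r * np.cos(theta)
    ys = r0 * r * ecc * np.sin(theta)
    x = cx + xs * np.cos(rot) - ys * np.sin(rot)
    y = cy + xs * np.sin(rot) + ys * np.cos(rot)
    return np.column_stack([x, y])


def generate_synthetic_samples(cfg: SynthConfig) -> list[ImageSample]:
    """Deterministic in-memory synthetic fundus dataset."""
    rng = np.random.default_rng(cfg.seed)
    s = cfg.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64) + 0.5
    samples = []
    for idx in range(cfg.n_images):
        bg_lo, bg_hi = cfg.background_intensity_range
        img = rng.uniform(bg_lo, bg_hi, size=(s, s, 3))
        # circular fundus field with a radial falloff, reddish hue
        fr = 0.5 * cfg.fundus_radius_fraction * s
        fcx = s / 2 + rng.uniform(-0.02, 0.02) * s
        fcy = s / 2 + rng.uniform(-0.02, 0.02) * s
        dist = np.hypot(xx - fcx, yy - fcy)
        field = dist < fr
        fall = np.clip(1.0 - (dist / fr) ** 2, 0, 1)
        base = np.array([rng.uniform(150, 195), rng.uniform(60, 95),
                         rng.uniform(25, 45)])
        for c in range(3):
            img[..., c] = np.where(field, base[c] * (0.55 + 0.45 * fall),
                                   img[..., c])
        # optic disc: bright ellipse placed off-centre
        dcx = fcx + rng.choice([-1, 1]) * rng.uniform(0.18, 0.30) * fr
        dcy = fcy + rng.uniform(-0.12, 0.12) * fr
        dr = rng.uniform(0.09, 0.13) * fr
        disc = (((xx - dcx) / dr) ** 2 + ((yy - dcy) / (dr * rng.uniform(0.85, 1.0))) ** 2) < 1
        disc_col = np.array([rng.uniform(225, 250), rng.uniform(200, 230),
                             rng.uniform(120, 160)])
        for c in range(3):
            img[..., c] = np.where(disc, disc_col[c], img[..., c])
        # a few dark vessels radiating from the disc
        for _ in range(4):
            ang = rng.uniform(0, 2 * np.pi)
            curv = rng.uniform(-0.6, 0.6)
            t = np.linspace(0, 1, 80)
            vx = dcx + np.cos(ang + curv * t) * t * fr * 0.9
            vy = dcy + np.sin(ang + curv * t) * t * fr * 0.9
            wd = rng.uniform(1.0, 2.0)
            for px_, py_ in zip(vx, vy):
                x0, x1 = int(px_ - wd), int(px_ + wd) + 1
                y0, y1 = int(py_ - wd), int(py_ + wd) + 1
                if 0 <= x0 and x1 <= s and 0 <= y0 and y1 <= s:
                    img[y0:y1, x0:x1] *= 0.65
        # lesions: bright irregular patches near the disc
        instances = []
        lesion_free = rng.uniform() < cfg.lesion_free_fraction
        n_lesions = 0 if lesion_free else int(
            rng.integers(cfg.lesions_per_image[0], cfg.lesions_per_image[1] + 1))
        li_lo, li_hi = cfg.lesion_intensity_range
        for _ in range(n_lesions):
            for _attempt in range(20):
                ang = rng.uniform(0, 2 * np.pi)
                dist_c = rng.uniform(1.0, 2.8) * dr
                lcx = dcx + np.cos(ang) * dist_c
                lcy = dcy + np.sin(ang) * dist_c
                r0 = rng.uniform(0.055, 0.16) * s
                poly_px = _lesion_polygon(rng, lcx, lcy, r0)
                poly = poly_px / s
                if poly.min() < 0.005 or poly.max() > 0.995:
                    continue
                # freeze label precision first so the stored raster matches
                # a re-rasterisation of the written label exactly
                poly = np.round(np.clip(poly, 0.0, 1.0), 6)
                mask = polygon_to_mask(poly, s, s)
                if mask.sum() >= 9:
                    break
            else:
                continue
            shade = rng.uniform(li_lo, li_hi)
            col = np.array([shade, shade * rng.uniform(0.88, 0.98),
                            shade * rng.uniform(0.55, 0.75)])
            tex = rng.uniform(0.92, 1.0, size=(s, s))
            for c in range(3):
                img[..., c] = np.where(mask, col[c] * tex, img[..., c])
            cls = 0
            if cfg.n_classes == 2 and dist_c < 1.6 * dr + r0:
                cls = 1  # peripapillary (contiguous with the disc region)
            instances.append(InstanceAnnotation(cls, poly))
        img += rng.normal(0, 2.0, size=img.shape)
        samples.append(ImageSample(f"synth_{idx:04d}",
                                   np.clip(img, 0, 255).astype(np.uint8),
                                   instances))
    return samples


def generate_synthetic_fundus(cfg: SynthConfig, out_dir) -> DatasetManifest:
    """Write a synthetic dataset (PNG images + YOLO-seg labels + manifest)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    samples = generate_synthetic_samples(cfg)
    images, labels = [], []
    for smp in samples:
        img_path = out / "images" / f"{smp.id}.png"
        lbl_path = out / "labels" / f"{smp.id}.txt"
        Image.fromarray(smp.image).save(img_path)
        write_labels(smp.instances, lbl_path)
        images.append(str(img_path.relative_to(out)))
        labels.append(str(lbl_path.relative_to(out)))
    manifest = DatasetManifest(root=str(out), images=images, labels=labels)
    manifest.save(out / "manifest.yaml")
    return manifest


def load_samples(manifest: DatasetManifest) -> list[ImageSample]:
    root = Path(manifest.root)
    samples = []
    for img_rel, lbl_rel in zip(manifest.images, manifest.labels):
        img = np.asarray(Image.open(root / img_rel).convert("RGB"))
        anns = read_labels(root / lbl_rel)
        samples.append(ImageSample(Path(img_rel).stem, img, anns))
    return samples
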