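"""Datasets: image-folder reading, stratified splitting, augmentation and
a seeded synthetic leaf-image generator.

Images are float32 RGB arrays in [0, 1] with (H, W, 3) layout; the network
consumes NCHW batches built by :func:`to_batch`.  The folder layout is one
subdirectory per class (the layout public leaf datasets ship in), read in
deterministic lexicographic order.

The synthetic generator draws leaf-like images — an elliptical green lamina
with a midrib and lateral veins on a soil-toned background — and stamps a
class-specific discoloration motif (uniform, marginal or interveinal
chlorosis, necrotic spotting, purpling, mottling or combinations) for each
of ten nutrient-status classes, so the whole pipeline is testable without
any download.  Generation is a pure function of the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")

#: class names mirroring the ten nutrient-status categories of public
#: coffee-leaf deficiency data, in sorted (reader) order
DEFAULT_CLASSES = (
    "boron", "calcium", "healthy", "iron", "magnesium",
    "manganese", "multiple", "nitrogen", "phosphorus", "potassium",
)


@dataclass
class LabeledDataset:
    """Ordered (image, class-index) pairs with class names and assignments.

    ``items`` holds either file paths (lazy) or in-memory arrays.  ``split``
    maps item index -> split name, ``fold`` maps item index -> fold number;
    an item carries at most one assignment per scheme.
    """

    items: list  # list[tuple[Path | np.ndarray, int]]
    class_names: tuple[str, ...]
    image_size: int = 224
    split: dict = field(default_factory=dict)
    fold: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        for _, label in self.items:
            if not 0 <= label < len(self.class_names):
                raise ValueError(f"class index {label} out of range")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.items], dtype=np.int64)

    def image(self, i: int) -> np.ndarray:
        src, _ = self.items[i]
        if isinstance(src, np.ndarray):
            return src
        return load_image(src, self.image_size)

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        indices = list(indices)
        return LabeledDataset([self.items[i] for i in indices], self.class_names,
                              self.image_size)

    def split_subset(self, name: str) -> "LabeledDataset":
        return self.subset(i for i in range(len(self)) if self.split.get(i) == name)

    def fold_subset(self, k: int, complement: bool = False) -> "LabeledDataset":
        keep = (lambda f: f != k) if complement else (lambda f: f == k)
        return self.subset(i for i in range(len(self)) if keep(self.fold.get(i)))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Materialize all images as (N, H, W, 3) plus the label vector."""
        imgs = np.stack([self.image(i) for i in range(len(self))])
        return imgs, self.labels


def load_image(path: Path | str, image_size: int = 224) -> np.ndarray:
    """Read one image, bilinear-resize to square ``image_size``, scale to [0,1]."""
    with Image.open(path) as im:
        im = im.convert("RGB").resize((image_size, image_size), Image.BILINEAR)
        return np.asarray(im, dtype=np.float32) / 255.0


def to_batch(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) in [0,1] -> network-layout (N, 3, H, W) float32."""
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2), dtype=np.float32)


def load_image_folder(root: Path | str, image_size: int = 224) -> LabeledDataset:
    """Read a one-directory-per-class image tree, lexicographically ordered.

    Unreadable files are skipped with a logged count; an empty tree is an
    error.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    class_names = tuple(d.name for d in class_dirs)
    items: list = []
    skipped = 0
    for label, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if not f.is_file():
                continue
            try:
                with Image.open(f) as im:
                    im.verify()
            except Exception:
                skipped += 1
                continue
            items.append((f, label))
    if skipped:
        logger.warning("skipped %d unreadable image files under %s", skipped, root)
    if not items:
        raise ValueError(f"no readable images under {root}")
    return LabeledDataset(items, class_names, image_size)


# -- splitting ---------------------------------------------------------------

def largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion ``n`` items to parts by ratio with largest-remainder rounding.

    Ties in the remainders are broken by part order (earlier part wins).
    """
    quotas = [n * r for r in ratios]
    counts = [int(q) for q in quotas]
    leftovers = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftovers]:
        counts[i] += 1
    return counts


def split_dataset(ds: LabeledDataset, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> LabeledDataset:
    """Stratified train/val/test assignment.

    Each class is shuffled with the seed and apportioned by the ratios
    using largest-remainder rounding, so splits are disjoint, exhaustive
    and class-balanced.
    """
    if len(ratios) != 3 or any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be three positive numbers summing to 1")
    rng = np.random.default_rng(seed)
    labels = ds.labels
    ds.split = {}
    for c in range(len(ds.class_names)):
        idx = np.flatnonzero(labels == c)
        if len(idx) and len(idx) < len(SPLITS):
            raise ValueError(f"class {ds.class_names[c]!r} has fewer items than splits")
        rng.shuffle(idx)
        counts = largest_remainder(len(idx), ratios)
        start = 0
        for name, cnt in zip(SPLITS, counts):
            for i in idx[start:start + cnt]:
                ds.split[int(i)] = name
            start += cnt
    return ds


def make_folds(ds: LabeledDataset, k: int = 5, seed: int = 0) -> LabeledDataset:
    """Stratified k-fold assignment: per class, fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    labels = ds.labels
    ds.fold = {}
    for c in range(len(ds.class_names)):
        idx = np.flatnonzero(labels == c)
        if len(idx) and len(idx) < k:
            raise ValueError(f"class {ds.class_names[c]!r} has fewer items than folds")
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            for i in chunk:
                ds.fold[int(i)] = f
    return ds


# -- augmentation ------------------------------------------------------------

@dataclass
class AugmentConfig:
    """On-the-fly augmentation: flips, right-angle rotations, photometric
    jitter and additive Gaussian noise, applied to the ``apply_to`` splits."""

    hflip: float = 0.5
    vflip: float = 0.5
    rotations: tuple[int, ...] = (90, 180, 270)
    rotation_prob: float = 0.5
    brightness_delta: float = 0.1
    contrast_range: tuple[float, float] = (0.8, 1.2)
    noise_sigma: float = 0.02
    noise_prob: float = 0.5
    apply_to: tuple[str, ...] = ("train",)

    def __post_init__(self):
        for p in (self.hflip, self.vflip, self.rotation_prob, self.noise_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(r not in (90, 180, 270) for r in self.rotations):
            raise ValueError("rotations must be a subset of {90, 180, 270}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def augment_image(img: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to an (H, W, 3) image."""
    if img.ndim != 3 or img.shape[2] != 3 or not np.isfinite(img).all():
        raise ValueError("expected a finite (H, W, 3) image")
    out = img
    if cfg.hflip > 0 and rng.random() < cfg.hflip:
        out = out[:, ::-1]
    if cfg.vflip > 0 and rng.random() < cfg.vflip:
        out = out[::-1]
    if cfg.rotations and rng.random() < cfg.rotation_prob:
        deg = cfg.rotations[rng.integers(len(cfg.rotations))]
        out = np.rot90(out, k=deg // 90)
    if cfg.brightness_delta > 0:
        out = out + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta)
    lo, hi = cfg.contrast_range
    if (lo, hi) != (1.0, 1.0):
        factor = rng.uniform(lo, hi)
        mean = out.mean()
        out = (out - mean) * factor + mean
    if cfg.noise_sigma > 0 and rng.random() < cfg.noise_prob:
        out = out + rng.normal(0.0, cfg.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


# -- synthetic leaf images ---------------------------------------------------

#: discoloration motif per class
CLASS_PATTERNS = {
    "boron": "necrotic_tip",
    "calcium": "marginal_pale",
    "healthy": "healthy",
    "iron": "interveinal_pale",
    "magnesium": "interveinal_orange",
    "manganese": "mottling",
    "multiple": "multi",
    "nitrogen": "uniform_chlorosis",
    "phosphorus": "purpling",
    "potassium": "marginal_chlorosis",
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic leaf-image generator."""

    num_per_class: int = 8
    image_size: int = 224
    seed: int = 0
    class_patterns: dict = field(default_factory=lambda: dict(CLASS_PATTERNS))

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32 pixels")
        if self.num_per_class < 1:
            raise ValueError("num_per_class must be positive")


def _leaf_geometry(s: int, rng: np.random.Generator):
    """Lamina mask, normalized radial coordinate and vein mask for one leaf."""
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32) / (s - 1) - 0.5
    # mild random pose: elongation and tilt
    ang = rng.uniform(-0.5, 0.5)
    ca, sa = np.cos(ang), np.sin(ang)
    u = ca * xx + sa * yy
    v = -sa * xx + ca * yy
    a = rng.uniform(0.30, 0.40)           # semi-minor (across the leaf)
    b = rng.uniform(0.42, 0.48)           # semi-major (along the midrib)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    lamina = r < 1.0
    # midrib along v, lateral veins branching at ~40 degrees
    midrib = (np.abs(u) < 0.012) & lamina
    veins = midrib.copy()
    for t in np.linspace(-0.8, 0.8, 9):
        d = np.abs((v - t * b) - np.sign(u) * 0.9 * np.abs(u))
        veins |= (d < 0.008) & lamina
    return lamina, np.clip(r, 0.0, 1.5), veins, v / b


def _spot_mask(s: int, rng: np.random.Generator, n_spots: int,
               rad_range=(0.03, 0.06)) -> np.ndarray:
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32) / (s - 1)
    spots = np.zeros((s, s), bool)
    for _ in range(n_spots):
        cy, cx = rng.uniform(0.15, 0.85, 2)
        rad = rng.uniform(*rad_range)
        spots |= (yy - cy) ** 2 + (xx - cx) ** 2 < rad ** 2
    return spots


def _apply_motif(img, lamina, r, axial, veins, motif, rng):
    """Stamp a discoloration motif onto the lamina, in place.

    Colors and coverages are deliberately distinct between motifs so the
    ten classes form separable clusters in simple color/texture statistics.
    """
    yellow = np.array([0.82, 0.74, 0.10], np.float32)
    pale = np.array([0.90, 0.90, 0.62], np.float32)
    white = np.array([0.93, 0.93, 0.85], np.float32)
    orange = np.array([0.88, 0.50, 0.08], np.float32)
    brown = np.array([0.30, 0.18, 0.06], np.float32)
    purple = np.array([0.45, 0.12, 0.52], np.float32)
    s = img.shape[0]

    def blend(mask, color, strength):
        m = (mask & lamina).astype(np.float32)[..., None] * strength
        img[:] = img * (1 - m) + color * m

    interveinal = lamina & ~veins
    if motif == "healthy":
        return
    if motif == "uniform_chlorosis":
        blend(lamina, yellow, rng.uniform(0.80, 0.90))
    elif motif == "marginal_chlorosis":
        # chlorotic band with a necrotic rim at the very edge
        blend(r > rng.uniform(0.60, 0.66), yellow, 0.9)
        blend(r > 0.88, brown, 0.9)
    elif motif == "marginal_pale":
        blend(r > rng.uniform(0.55, 0.61), white, 0.9)
    elif motif == "interveinal_pale":
        blend(interveinal, pale, rng.uniform(0.80, 0.90))
    elif motif == "interveinal_orange":
        blend(interveinal & (r > 0.25), orange, rng.uniform(0.70, 0.80))
    elif motif == "mottling":
        blend(_spot_mask(s, rng, 35) & interveinal, yellow, 0.95)
    elif motif == "necrotic_tip":
        # large corky patches toward the tip, each ringed by a chlorotic halo
        yy, xx = np.mgrid[0:s, 0:s].astype(np.float32) / (s - 1)
        spots = np.zeros((s, s), bool)
        halo = np.zeros((s, s), bool)
        for _ in range(35):
            cy, cx = rng.uniform(0.15, 0.85, 2)
            rad = rng.uniform(0.05, 0.10)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            spots |= d2 < rad ** 2
            halo |= d2 < (1.5 * rad) ** 2
        tipward = axial > -0.2
        blend(halo & ~spots & tipward, yellow, 0.6)
        blend(spots & tipward, brown, 0.95)
    elif motif == "purpling":
        blend(interveinal, purple, rng.uniform(0.65, 0.75))
    elif motif == "multi":
        # co-occurring symptoms: chlorotic margin, pale center, necrosis
        blend(r > 0.60, yellow, 0.9)
        blend(interveinal & (r <= 0.60), pale, 0.55)
        blend(_spot_mask(s, rng, 22, (0.04, 0.08)), brown, 0.9)
    else:
        raise ValueError(f"unknown motif {motif!r}")


def generate_synthetic(spec: SyntheticSpec | None = None) -> LabeledDataset:
    """Seeded synthetic leaf dataset with class-specific discoloration motifs."""
    spec = spec or SyntheticSpec()
    class_names = tuple(sorted(spec.class_patterns))
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    items = []
    for label, name in enumerate(class_names):
        motif = spec.class_patterns[name]
        for _ in range(spec.num_per_class):
            img = np.empty((s, s, 3), np.float32)
            img[:] = np.array([0.45, 0.36, 0.26]) + rng.normal(0, 0.02, 3)  # soil
            lamina, r, veins, axial = _leaf_geometry(s, rng)
            green = np.array([0.13, 0.42, 0.10], np.float32) + rng.normal(0, 0.02, 3)
            img[lamina] = green
            img[veins] = green * 0.6
            _apply_motif(img, lamina, r, axial, veins, motif, rng)
            img += rng.normal(0.0, 0.015, img.shape)       # sensor noise
            items.append((np.clip(img, 0.0, 1.0).astype(np.float32), label))
    return LabeledDataset(items, class_names, spec.image_size)


def export_image_folder(ds: LabeledDataset, root: Path | str) -> None:
    """Write a dataset to the one-directory-per-class layout as PNG files."""
    root = Path(root)
    counters = {}
    for i in range(len(ds)):
        _, label = ds.items[i]
        name = ds.class_names[label]
        d = root / name
        d.mkdir(parents=True, exist_ok=True)
        counters[name] = counters.get(name, 0) + 1
        arr = (ds.image(i) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(d / f"{name}_{counters[name]:04d}.png")


def write_manifest(ds: LabeledDataset, path: Path | str) -> None:
    """CSV manifest of (item, class, split, fold)."""
    with open(path, "w") as fh:
        fh.write("item,class,split,fold\n")
        for i, (src, label) in enumerate(ds.items):
            name = src if isinstance(src, (str, Path)) else f"array:{i}"
            fh.write(f"{name},{ds.class_names[label]},"
                     f"{ds.split.get(i, '')},{ds.fold.get(i, '')}\n")
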