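"""Dataset I/O, synthetic chest-X-ray-like fixtures, and augmentation.

The on-disk layout mirrors the public pediatric pneumonia datasets:
``<root>/{train,test,validation}/{bacterial,normal,viral}/*.jpeg|png``
with grayscale images rescaled to [0, 1].  Class indices are assigned from
the *sorted* class-folder names so labels are platform independent:
bacterial=0, normal=1, viral=2.

The synthetic generator emulates the three radiographic classes with
distinct structural motifs on a smooth thorax-like background:

* ``bacterial`` — a single bright focal consolidation (Gaussian blob with
  jittered position, size and intensity);
* ``normal``   — the plain background with mild brightness jitter;
* ``viral``    — a diffuse perihilar haze plus fine oriented streaking
  (interstitial-pattern stand-in) with jittered frequency and phase.

It is a pure function of its configuration, so fixtures are reproducible
bit-for-bit from a seed.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import DataError

CLASS_NAMES: tuple[str, ...] = ("bacterial", "normal", "viral")
SPLIT_NAMES: tuple[str, ...] = ("train", "test", "validation")
_IMAGE_EXTENSIONS = {".jpeg", ".jpg", ".png"}


# ---------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------

@dataclass
class ImageBatch:
    """A stack of grayscale images with per-image labels and stable ids.

    ``pixels`` is ``(n, h, w, 1)`` float32 in [0, 1]; ``labels`` are class
    indices (bacterial=0, normal=1, viral=2); ``ids`` are stable per-image
    identifier strings.
    """

    pixels: np.ndarray
    labels: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.ids = tuple(str(i) for i in self.ids)
        if self.pixels.ndim != 4 or self.pixels.shape[-1] != 1:
            raise DataError(f"pixels must be (n, h, w, 1); got {self.pixels.shape}")
        n = self.pixels.shape[0]
        if len(self.labels) != n or len(self.ids) != n:
            raise DataError(
                f"inconsistent batch: {n} images, {len(self.labels)} labels, "
                f"{len(self.ids)} ids")
        if n and (self.pixels.min() < 0.0 or self.pixels.max() > 1.0):
            raise DataError("pixel values must lie in [0, 1]")
        if n and not np.isin(self.labels, np.arange(len(CLASS_NAMES))).all():
            raise DataError(f"labels must be in 0..{len(CLASS_NAMES) - 1}")

    def __len__(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def image_size(self) -> int:
        return int(self.pixels.shape[1])

    def subset(self, index: np.ndarray | list[int]) -> "ImageBatch":
        index = np.asarray(index)
        return ImageBatch(self.pixels[index], self.labels[index],
                          tuple(self.ids[i] for i in index))

    def select_class(self, label: int) -> "ImageBatch":
        return self.subset(np.flatnonzero(self.labels == label))

    @staticmethod
    def concatenate(batches: list["ImageBatch"]) -> "ImageBatch":
        return ImageBatch(
            np.concatenate([b.pixels for b in batches]),
            np.concatenate([b.labels for b in batches]),
            tuple(i for b in batches for i in b.ids))


@dataclass
class DatasetSplits:
    """Train / test / validation batches with disjoint image ids."""

    train: ImageBatch
    test: ImageBatch
    validation: ImageBatch

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name in SPLIT_NAMES:
            ids = set(getattr(self, name).ids)
            if seen & ids:
                raise DataError(f"split '{name}' shares ids with another split")
            seen |= ids

    def split(self, name: str) -> ImageBatch:
        if name not in SPLIT_NAMES:
            raise DataError(f"unknown split '{name}'")
        return getattr(self, name)


@dataclass
class SyntheticConfig:
    """Conditions for the synthetic benchmark generator.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 100 images per class per split at 64x64 with pixel noise of
    sd 0.03, seed 7.
    """

    n_per_class_per_split: dict[str, int] = field(
        default_factory=lambda: {"train": 100, "test": 100, "validation": 100})
    image_size: int = 64
    noise_sd: float = 0.03
    seed: int = 7

    def __post_init__(self) -> None:
        for split in SPLIT_NAMES:
            if self.n_per_class_per_split.get(split, 0) < 1:
                raise DataError(f"count for split '{split}' must be >= 1")
        if self.image_size < 16:
            raise DataError("image_size must be >= 16")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")


@dataclass
class AugmentConfig:
    """Bounds for random rotation / scaling / translation."""

    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise DataError("scale_range must satisfy 0 < min <= max")
        if not 0.0 <= self.translate_frac <= 0.5:
            raise DataError("translate_frac must lie in [0, 0.5]")


# ---------------------------------------------------------------------
# folder I/O
# ---------------------------------------------------------------------

def _load_one(path: Path, image_size: int) -> np.ndarray:
    try:
        with Image.open(path) as img:
            img = img.convert("L")
            if img.size != (image_size, image_size):
                img = img.resize((image_size, image_size), Image.BILINEAR)
            arr = np.asarray(img, dtype=np.float32) / 255.0
    except (UnidentifiedImageError, OSError) as exc:
        raise DataError(f"cannot decode image file {path}: {exc}") from exc
    return arr[..., None]


def load_image_folder(root: str | Path, image_size: int = 224) -> DatasetSplits:
    """Load a `train/test/validation` x class-folder hierarchy.

    Images are decoded to grayscale, resized to ``image_size`` square and
    rescaled to [0, 1].  Labels come from the class subdirectory name in
    sorted order, never from filesystem enumeration order.
    """
    root = Path(root)
    batches = {}
    for split in SPLIT_NAMES:
        split_dir = root / split
        if not split_dir.is_dir():
            raise DataError(f"missing split directory: {split_dir}")
        pixels, labels, ids = [], [], []
        for label, cls in enumerate(CLASS_NAMES):
            cls_dir = split_dir / cls
            if not cls_dir.is_dir():
                raise DataError(f"missing class directory: {cls_dir}")
            files = sorted(p for p in cls_dir.iterdir()
                           if p.suffix.lower() in _IMAGE_EXTENSIONS)
            for path in files:
                pixels.append(_load_one(path, image_size))
                labels.append(label)
                ids.append(f"{split}/{cls}/{path.stem}")
        if not pixels:
            pixels_arr = np.zeros((0, image_size, image_size, 1), np.float32)
        else:
            pixels_arr = np.stack(pixels)
        batches[split] = ImageBatch(pixels_arr, np.asarray(labels, np.int64),
                                    tuple(ids))
    return DatasetSplits(**batches)


# ---------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------

def _background(size: int) -> np.ndarray:
    yy = np.linspace(0.0, 1.0, size, dtype=np.float32)[:, None]
    xx = np.linspace(0.0, 1.0, size, dtype=np.float32)[None, :]
    base = 0.30 + 0.25 * yy + 0.0 * xx
    # mild vignette so edges are darker, as on a radiograph
    r2 = (yy - 0.5) ** 2 + (xx - 0.5) ** 2
    return base - 0.15 * r2.astype(np.float32)


def _synth_image(label: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """One image: class motif + documented per-image jitter (no pixel noise)."""
    yy = np.linspace(0.0, 1.0, size, dtype=np.float32)[:, None]
    xx = np.linspace(0.0, 1.0, size, dtype=np.float32)[None, :]
    img = _background(size).copy()
    # brightness jitter is common to all classes
    img += rng.uniform(-0.02, 0.02)
    if label == 0:  # bacterial: focal consolidation
        cy, cx = rng.uniform(0.35, 0.65, size=2)
        sig = rng.uniform(0.14, 0.20)
        amp = rng.uniform(0.50, 0.65)
        img += amp * np.exp(-(((yy - cy) ** 2) + ((xx - cx) ** 2))
                            / (2.0 * sig * sig)).astype(np.float32)
    elif label == 2:  # viral: diffuse haze + fine oriented streaking
        img += 0.18 * np.exp(-((yy - 0.5) ** 2) / (2 * 0.25 ** 2)).astype(np.float32)
        freq = rng.uniform(6.0, 9.0)
        theta = rng.uniform(0.5, 1.1)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.cos(theta) * xx + np.sin(theta) * yy
        img += 0.12 * np.sin(2.0 * np.pi * freq * wave + phase).astype(np.float32)
    # label == 1 (normal): background only
    return img


def make_synthetic_dataset(config: SyntheticConfig) -> DatasetSplits:
    """Generate a reproducible three-class benchmark dataset.

    Bit-identical output for identical ``config`` (including seed): each
    (split, class) stream draws from its own child of the config seed, so
    changing one split's count does not perturb the others.
    """
    batches = {}
    for si, split in enumerate(SPLIT_NAMES):
        n = config.n_per_class_per_split[split]
        pixels, labels, ids = [], [], []
        for label in range(len(CLASS_NAMES)):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, si, label]))
            for i in range(n):
                img = _synth_image(label, config.image_size, rng)
                if config.noise_sd > 0:
                    # per-image exposure variation: the realized noise level
                    # varies around noise_sd so classifiers cannot key on an
                    # exact noise energy
                    sd = config.noise_sd * rng.uniform(0.5, 1.5)
                    img = img + rng.normal(0.0, sd, img.shape).astype(np.float32)
                pixels.append(np.clip(img, 0.0, 1.0)[..., None])
                labels.append(label)
                ids.append(f"{split}/{CLASS_NAMES[label]}/{i:04d}")
        batches[split] = ImageBatch(np.stack(pixels).astype(np.float32),
                                    np.asarray(labels, np.int64), tuple(ids))
    return DatasetSplits(**batches)


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

def augment(batch: ImageBatch, config: AugmentConfig) -> ImageBatch:
    """Random rotation / scaling / translation per image, clipped to [0, 1].

    Parameters are drawn independently per image from the seeded generator
    within the config bounds; labels and ids pass through unchanged.  The
    degenerate config (0 deg, scale (1,1), shift 0) is the exact identity.
    """
    rng = np.random.default_rng(config.seed)
    size = batch.image_size
    out = np.empty_like(batch.pixels)
    center = (size - 1) / 2.0
    for i in range(len(batch)):
        angle = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
        scale = rng.uniform(*config.scale_range)
        ty, tx = rng.uniform(-config.translate_frac, config.translate_frac,
                             size=2) * size
        c, s = np.cos(angle), np.sin(angle)
        # output->input mapping: rotate by -angle, divide by scale
        mat = np.array([[c, -s], [s, c]]) / scale
        offset = np.array([center, center]) - mat @ np.array(
            [center + ty, center + tx])
        img = ndimage.affine_transform(
            batch.pixels[i, :, :, 0], mat, offset=offset, order=1,
            mode="constant", cval=0.0)
        out[i, :, :, 0] = np.clip(img, 0.0, 1.0)
    return ImageBatch(out, batch.labels.copy(), batch.ids)


def write_dataset_folder(splits: DatasetSplits, root: str | Path, *,
                         codec: str = "png", overwrite: bool = False) -> dict:
    """Persist splits in the standard split/class folder layout.

    Returns a manifest of per-(split, class) counts; also written as
    ``manifest.json`` under ``root``.
    """
    if codec not in ("png", "jpeg"):
        raise DataError(f"unsupported codec '{codec}'")
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise DataError(f"target folder {root} exists and is non-empty; "
                            "pass overwrite=True to replace it")
        shutil.rmtree(root)
    counts: dict[str, int] = {}
    for split in SPLIT_NAMES:
        batch = splits.split(split)
        for label, cls in enumerate(CLASS_NAMES):
            sub = batch.select_class(label)
            folder = root / split / cls
            folder.mkdir(parents=True, exist_ok=True)
            for i in range(len(sub)):
                stem = sub.ids[i].replace("/", "_")
                img = Image.fromarray(
                    np.round(sub.pixels[i, :, :, 0] * 255.0).astype(np.uint8),
                    "L")
                img.save(folder / f"{stem}.{codec}")
            counts[f"{split}/{cls}"] = len(sub)
    manifest = {"codec": codec, "folders": counts,
                "total": int(sum(counts.values()))}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------
# attack hierarchy writer
# ---------------------------------------------------------------------

def write_attack_hierarchy(adv: dict, root: str | Path, *, codec: str = "png",
                           overwrite: bool = False) -> dict:
    """Persist attacked images as one folder tree per (attack family, eps).

    ``adv`` maps ``(family, epsilon, split, class_name) -> ImageBatch``.
    Layout: ``<root>/attacks/<family>/eps_<value>/<split>/<class>/<id>.<ext>``.
    Returns (and writes as JSON) a manifest of per-folder counts and the
    codec.  PNG is the default because lossy JPEG re-encoding perturbs
    eps-bounded pixels.
    """
    if codec not in ("png", "jpeg"):
        raise DataError(f"unsupported codec '{codec}'")
    root = Path(root)
    target = root / "attacks"
    if target.exists() and any(target.iterdir()):
        if not overwrite:
            raise DataError(
                f"target folder {target} exists and is non-empty; "
                "pass overwrite=True to replace it")
        shutil.rmtree(target)
    folders: dict[str, int] = {}
    family_totals: dict[str, int] = {}
    for (family, eps, split, cls), batch in adv.items():
        if cls not in CLASS_NAMES:
            raise DataError(f"unknown class '{cls}'")
        folder = target / family / f"eps_{eps:g}" / split / cls
        folder.mkdir(parents=True, exist_ok=True)
        for i in range(len(batch)):
            stem = batch.ids[i].replace("/", "_")
            img = Image.fromarray(
                np.round(batch.pixels[i, :, :, 0] * 255.0).astype(np.uint8), "L")
            img.save(folder / f"{stem}.{codec}")
        key = f"{family}/eps_{eps:g}"
        folders[key] = folders.get(key, 0) + len(batch)
        family_totals[family] = family_totals.get(family, 0) + len(batch)
    manifest = {
        "codec": codec,
        "folders": dict(sorted(folders.items())),
        "per_family_total": dict(sorted(family_totals.items())),
        "total": int(sum(folders.values())),
    }
    target.mkdir(parents=True, exist_ok=True)
    (target / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
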