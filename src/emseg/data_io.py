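"""Dataset plumbing: images, masks, manifests, splits and augmentations.

Images are 8- or 16-bit PNG/TIFF, grayscale or RGB.  Masks are
single-channel indexed PNGs whose pixel value is the 0-based class index,
with class 0 reserved for background (background is itself a segmentation
class here, since everything that is not an organelle of interest still has
to be labelled).  A dataset is described by a CSV manifest with header
``id,image,mask`` plus a YAML sidecar that declares the class names in
index order; all paths are resolved relative to the manifest.

The hold-out split is a simple (non-stratified) random 8:2 partition with
``train = floor(fraction * N)``, and model selection uses repeated k-fold
cross-validation (5 x 5 by default) on the training partition only.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

__all__ = [
    "ClassScheme", "LabeledSample", "DatasetManifest", "FoldPlan",
    "ClassWeights", "ManifestError", "load_manifest", "save_manifest",
    "load_sample", "save_sample", "split_holdout", "make_cv_folds",
    "compute_class_weights", "augment_sample", "AUGMENTATIONS",
]


class ManifestError(ValueError):
    """Raised when a manifest or one of its samples fails validation."""


@dataclass(frozen=True)
class ClassScheme:
    """Ordered segmentation classes; index 0 is always background."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) < 2:
            raise ValueError("a class scheme needs at least 2 classes")
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        if self.names[0] != "background":
            raise ValueError("index 0 must be the background class")

    @property
    def n_classes(self) -> int:
        return len(self.names)


@dataclass
class LabeledSample:
    """One image with its per-pixel integer class mask."""

    id: str
    image: np.ndarray
    mask: np.ndarray

    def validate(self, n_classes: int) -> "LabeledSample":
        if self.image.shape[:2] != self.mask.shape:
            raise ManifestError(
                f"sample {self.id!r}: image {self.image.shape[:2]} and mask "
                f"{self.mask.shape} disagree")
        if not np.issubdtype(self.mask.dtype, np.integer):
            raise ManifestError(f"sample {self.id!r}: mask must be integer-valued")
        if self.mask.min() < 0 or self.mask.max() >= n_classes:
            raise ManifestError(
                f"sample {self.id!r}: mask labels outside [0, {n_classes})")
        return self


@dataclass
class DatasetManifest:
    """List of (id, image path, mask path) records plus the class scheme."""

    samples: list[tuple[str, Path, Path]]
    scheme: ClassScheme

    def __len__(self) -> int:
        return len(self.samples)

    def ids(self) -> list[str]:
        return [s[0] for s in self.samples]

    def subset(self, ids) -> "DatasetManifest":
        wanted = set(ids)
        return DatasetManifest([s for s in self.samples if s[0] in wanted],
                               self.scheme)

    def load(self, index_or_id) -> LabeledSample:
        if isinstance(index_or_id, str):
            matches = [s for s in self.samples if s[0] == index_or_id]
            if not matches:
                raise KeyError(index_or_id)
            sid, img, msk = matches[0]
        else:
            sid, img, msk = self.samples[index_or_id]
        return load_sample(sid, img, msk).validate(self.scheme.n_classes)

    def iter_samples(self):
        for i in range(len(self)):
            yield self.load(i)


@dataclass(frozen=True)
class FoldPlan:
    """Repeated k-fold partition of the training ids."""

    repeats: int
    k: int
    assignments: tuple[tuple[tuple[str, ...], ...], ...]
    seed: int

    def folds(self, repeat: int):
        """Yield (train_ids, val_ids) pairs for one repeat."""
        parts = self.assignments[repeat]
        for i, val in enumerate(parts):
            train = tuple(x for j, p in enumerate(parts) if j != i for x in p)
            yield train, val


@dataclass(frozen=True)
class ClassWeights:
    """Per-class positive weights normalized to mean one."""

    weights: tuple[float, ...]

    def __post_init__(self):
        if any(w <= 0 for w in self.weights):
            raise ValueError("class weights must be strictly positive")
        if abs(float(np.mean(self.weights)) - 1.0) > 1e-9:
            raise ValueError("class weights must average to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_sample(sid: str, image_path: Path, mask_path: Path) -> LabeledSample:
    image = np.asarray(Image.open(image_path))
    mask = np.asarray(Image.open(mask_path))
    if mask.ndim != 2:
        raise ManifestError(f"sample {sid!r}: mask must be single-channel")
    return LabeledSample(sid, image, mask.astype(np.int32))


def save_sample(sample: LabeledSample, image_path: Path, mask_path: Path) -> None:
    img = sample.image
    if img.dtype != np.uint8 and img.dtype != np.uint16:
        img = np.clip(img, 0, 255).astype(np.uint8)
    Image.fromarray(img).save(image_path)
    Image.fromarray(sample.mask.astype(np.uint8), mode="L").save(mask_path)


def _sidecar_path(manifest_path: Path) -> Path:
    return manifest_path.with_suffix(".yaml")


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read ``id,image,mask`` CSV plus its class-scheme sidecar, validating
    that ids are unique and every referenced file exists."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ManifestError(f"missing class-scheme sidecar: {sidecar}")
    scheme = ClassScheme(tuple(yaml.safe_load(sidecar.read_text())["classes"]))
    samples: list[tuple[str, Path, Path]] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["id", "image", "mask"]:
            raise ManifestError("manifest header must be exactly id,image,mask")
        for row in reader:
            sid = row["id"]
            if sid in seen:
                raise ManifestError(f"duplicate sample id {sid!r}")
            seen.add(sid)
            img = (path.parent / row["image"]).resolve()
            msk = (path.parent / row["mask"]).resolve()
            if not img.exists():
                raise ManifestError(f"sample {sid!r}: missing image {img}")
            if not msk.exists():
                raise ManifestError(f"sample {sid!r}: missing mask {msk}")
            samples.append((sid, img, msk))
    return DatasetManifest(samples, scheme)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "mask"])
        base = path.parent.resolve()
        for sid, img, msk in manifest.samples:
            writer.writerow([sid,
                             os.path.relpath(Path(img).resolve(), base),
                             os.path.relpath(Path(msk).resolve(), base)])
    _sidecar_path(path).write_text(
        yaml.safe_dump({"classes": list(manifest.scheme.names)}))


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def split_holdout(manifest: DatasetManifest, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[DatasetManifest, DatasetManifest]:
    """Random hold-out split with ``|train| = floor(fraction * N)``."""
    n = len(manifest)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(np.floor(train_fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    ids = manifest.ids()
    train_ids = {ids[i] for i in order[:n_train]}
    train = manifest.subset(train_ids)
    test = manifest.subset(set(ids) - train_ids)
    return train, test


def make_cv_folds(train: DatasetManifest, k: int = 5, repeats: int = 5,
                  seed: int = 0) -> FoldPlan:
    """Repeated k-fold plan; folds are reshuffled between repeats and their
    sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = train.ids()
    if len(ids) < k:
        raise ValueError(f"cannot make {k} folds from {len(ids)} samples")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(repeats):
        order = rng.permutation(len(ids))
        folds = tuple(tuple(ids[i] for i in part)
                      for part in np.array_split(order, k))
        assignments.append(folds)
    return FoldPlan(repeats, k, tuple(assignments), seed)


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------

def compute_class_weights(manifest: DatasetManifest) -> ClassWeights:
    """Inverse-pixel-frequency weights rescaled to mean one."""
    counts = np.zeros(manifest.scheme.n_classes, dtype=np.int64)
    for sample in manifest.iter_samples():
        counts += np.bincount(sample.mask.ravel(),
                              minlength=manifest.scheme.n_classes)
    empty = [manifest.scheme.names[i] for i in np.nonzero(counts == 0)[0]]
    if empty:
        raise ValueError(f"classes with zero pixels in the dataset: {empty}")
    inv = 1.0 / counts
    inv = inv / inv.mean()
    return ClassWeights(tuple(float(w) for w in inv))


# ---------------------------------------------------------------------------
# Geometric augmentations
# ---------------------------------------------------------------------------

def _flip_v(img, mask, rng):
    return img[::-1].copy(), mask[::-1].copy()


def _flip_h(img, mask, rng):
    return img[:, ::-1].copy(), mask[:, ::-1].copy()


def _transpose(img, mask, rng):
    axes = (1, 0, 2) if img.ndim == 3 else (1, 0)
    return img.transpose(axes).copy(), mask.T.copy()


def _rotate(img, mask, rng):
    angle = float(rng.uniform(-90.0, 90.0))

    def rot(arr, order):
        if arr.ndim == 3:
            return np.stack([ndimage.rotate(arr[..., c], angle, reshape=False,
                                            order=order, mode="reflect")
                             for c in range(arr.shape[2])], axis=2)
        return ndimage.rotate(arr, angle, reshape=False, order=order,
                              mode="reflect")

    return rot(img, 1), rot(mask, 0).astype(mask.dtype)


def _grid_distortion(img, mask, rng, num_steps: int = 5,
                     distort_limit: float = 0.3):
    """Piecewise-linear stretch/compress of a uniform grid on each axis."""

    def axis_map(size: int) -> np.ndarray:
        nodes = np.linspace(0, size - 1, num_steps + 1)
        spans = np.diff(nodes) * (1.0 + rng.uniform(-distort_limit,
                                                    distort_limit, num_steps))
        warped = np.concatenate([[0.0], np.cumsum(spans)])
        warped *= (size - 1) / warped[-1]
        # source coordinate for each output pixel (inverse map by interp)
        return np.interp(np.arange(size), warped, nodes)

    src_y = axis_map(img.shape[0])
    src_x = axis_map(img.shape[1])
    yy = np.repeat(src_y, img.shape[1]).reshape(img.shape[:2])
    xx = np.tile(src_x, img.shape[0]).reshape(img.shape[:2])

    def remap(arr, order):
        if arr.ndim == 3:
            return np.stack([ndimage.map_coordinates(arr[..., c], [yy, xx],
                                                     order=order, mode="reflect")
                             for c in range(arr.shape[2])], axis=2)
        return ndimage.map_coordinates(arr, [yy, xx], order=order, mode="reflect")

    return remap(img, 1), remap(mask, 0).astype(mask.dtype)


AUGMENTATIONS = {
    "vertical_flip": _flip_v,
    "horizontal_flip": _flip_h,
    "random_rotate": _rotate,
    "transpose": _transpose,
    "grid_distortion": _grid_distortion,
}


def augment_sample(sample: LabeledSample, op_name: str, seed: int = 0) -> LabeledSample:
    """Apply one named geometric transform identically to image and mask.

    The mask is resampled nearest-neighbour, so its label alphabet is always
    a subset of the original; spatial dimensions are preserved.
    """
    if op_name not in AUGMENTATIONS:
        raise KeyError(f"unknown augmentation {op_name!r}; choose from "
                       f"{sorted(AUGMENTATIONS)}")
    rng = np.random.default_rng(seed)
    img, mask = AUGMENTATIONS[op_name](sample.image, sample.mask, rng)
    return LabeledSample(sample.id, img, mask)
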