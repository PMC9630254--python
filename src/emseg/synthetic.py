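"""Synthetic whole-cell EM phantoms with paired ground-truth masks.

Each phantom emulates the gross layout of an EM slice through a plastic-
embedded cell: a bright-ish embedding background, one large textured
cytoplasm blob, a darker nucleus ellipse inside it, and optionally a few
small high-contrast mitochondria-like ellipses in the cytoplasm.  Intensity
texture is low-pass-filtered noise; global contrast varies between samples
and Gaussian pixel noise is added on top.  Class indices: 0 background,
1 cytoplasm, 2 nucleus, 3 mitochondria (when ``n_classes`` is 4).

The generator is deterministic per seed and its geometry priors give the
pixel-fraction ordering background > cytoplasm > nucleus > mitochondria on
average, mirroring the prevalence imbalance of real organelle datasets.

``simulate_predictor`` turns a ground-truth mask into the probability map
of a hypothetical base-learner with a controllable corruption level, which
lets ensemble logic be exercised without training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import ClassScheme, DatasetManifest, LabeledSample, save_manifest, \
    save_sample

__all__ = ["SynthConfig", "generate_sample", "generate_dataset",
           "simulate_predictor", "scheme_for"]


@dataclass(frozen=True)
class SynthConfig:
    """Phantom parameters.

    image_size must be divisible by 32 (the network downsampling depth);
    noise_sd is the additive Gaussian sigma on a 0-255 intensity scale;
    texture_scale scales the low-frequency intensity texture; mitochondria
    count is drawn uniformly from ``n_mitochondria`` (inclusive range).
    """

    image_size: int = 64
    n_classes: int = 3
    noise_sd: float = 8.0
    texture_scale: float = 20.0
    n_mitochondria: tuple[int, int] = (1, 6)
    seed: int = 0

    def __post_init__(self):
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")
        if self.n_classes not in (3, 4):
            raise ValueError("n_classes must be 3 (bg/cyto/nucleus) or 4 (+mito)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def scheme_for(n_classes: int) -> ClassScheme:
    names = ("background", "cytoplasm", "nucleus", "mitochondria")[:n_classes]
    return ClassScheme(names)


def _ellipse_mask(size: int, cy, cx, ry, rx, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * x + sa * y
    v = -sa * x + ca * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _texture(size: int, rng, sigma: float, scale: float) -> np.ndarray:
    t = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma)
    sd = t.std()
    return t / sd * scale if sd > 0 else t


def generate_sample(config: SynthConfig, seed: int | None = None) -> LabeledSample:
    """Draw one phantom; deterministic for a given (config, seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s = config.image_size
    for _attempt in range(100):
        # cytoplasm: a large jittered ellipse roughly centred
        cy, cx = rng.uniform(0.42 * s, 0.58 * s, 2)
        ry = rng.uniform(0.26 * s, 0.36 * s)
        rx = rng.uniform(0.26 * s, 0.36 * s)
        cyto = _ellipse_mask(s, cy, cx, ry, rx, rng.uniform(0, np.pi))
        # nucleus: smaller, darker, inside the cell
        nry = rng.uniform(0.35, 0.55) * ry
        nrx = rng.uniform(0.35, 0.55) * rx
        ncy = cy + rng.uniform(-0.3, 0.3) * ry
        ncx = cx + rng.uniform(-0.3, 0.3) * rx
        nucleus = _ellipse_mask(s, ncy, ncx, nry, nrx, rng.uniform(0, np.pi))
        if not (nucleus & cyto).sum() or nucleus.sum() >= cyto.sum():
            continue
        nucleus &= cyto
        break
    else:
        raise RuntimeError("could not draw a nucleus inside the cell in 100 tries")

    mask = np.zeros((s, s), dtype=np.int32)
    mask[cyto] = 1
    mask[nucleus] = 2

    if config.n_classes == 4:
        n_mito = int(rng.integers(config.n_mitochondria[0],
                                  config.n_mitochondria[1] + 1))
        for _ in range(n_mito):
            mry = rng.uniform(0.02 * s, 0.05 * s) + 1.0
            mrx = mry * rng.uniform(1.2, 2.5)
            mcy = rng.uniform(cy - ry, cy + ry)
            mcx = rng.uniform(cx - rx, cx + rx)
            mito = _ellipse_mask(s, mcy, mcx, mry, mrx, rng.uniform(0, np.pi))
            mito &= mask == 1  # only on cytoplasm, never over the nucleus
            mask[mito] = 3

    base = np.choose(mask, [190.0, 120.0, 80.0, 50.0][:config.n_classes]
                     + [50.0] * (4 - config.n_classes))
    img = base + _texture(s, rng, sigma=s / 16, scale=config.texture_scale)
    img *= rng.uniform(0.85, 1.15)                       # contrast variation
    img += rng.normal(0.0, config.noise_sd, (s, s))      # pixel noise
    img = np.clip(img, 0, 255).astype(np.uint8)
    return LabeledSample(f"phantom_{config.seed if seed is None else seed:05d}",
                         img, mask)


def generate_dataset(config: SynthConfig, n: int, seed: int,
                     out_dir: str | Path) -> DatasetManifest:
    """Write ``n`` phantoms as PNG image/mask pairs plus a loadable manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = scheme_for(config.n_classes)
    samples = []
    # distinct per-sample seeds derived from the dataset seed
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    for i in range(n):
        sample = generate_sample(config, seed=int(child_seeds[i]))
        sid = f"phantom_{i:04d}"
        img_path = out_dir / f"{sid}.png"
        msk_path = out_dir / f"{sid}_mask.png"
        save_sample(LabeledSample(sid, sample.image, sample.mask),
                    img_path, msk_path)
        samples.append((sid, img_path.resolve(), msk_path.resolve()))
    manifest = DatasetManifest(samples, scheme)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def simulate_predictor(truth: np.ndarray, eta: float, seed: int = 0,
                       n_classes: int | None = None) -> np.ndarray:
    """Probability map of a simulated base-learner.

    ``(1 - eta) * one_hot(truth) + eta * Dirichlet(1)`` per pixel: eta=0 is
    an oracle, eta=1 is uninformative; expected Jaccard of the argmax decays
    monotonically in between.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    truth = np.asarray(truth)
    c = int(n_classes if n_classes is not None else truth.max() + 1)
    rng = np.random.default_rng(seed)
    onehot = np.eye(c)[truth]
    noise = rng.dirichlet(np.ones(c), size=truth.shape)
    return ((1.0 - eta) * onehot + eta * noise).astype(np.float32)
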