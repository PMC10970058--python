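"""Dataset layout, splitting, augmentation, and a synthetic candling-image
generator.

Preserved (century) eggs are graded under transmitted light: the egg sits on
a hole over a bright lamp in a dark box, and internal quality shows up as a
class-specific translucency pattern.  The five classes (in the fixed order
used everywhere in this package) are

* ``QP``  qualified — reddish/orange translucent albumen and air chamber,
  opaque yolk;
* ``PP``  pale — under-pickled, weak pale-yellow translucency;
* ``BYP`` broken yolk — ruptured yolk membrane, irregular yolk/albumen
  boundary;
* ``YYP`` yellow yolk — incomplete color transformation, yellow rim at the
  yolk edge;
* ``IP``  inferior — spoiled/liquefied interior, near-total opacity.

For sorting, the three substandard classes collapse onto one grade:
QP -> QP, {PP, BYP, YYP} -> SP, IP -> IP.

The real image set is private, so :func:`generate_synthetic_dataset` renders
a stylized stand-in for each phenotype — dark background, elliptical egg
silhouette, class-conditional interior — sufficient for end-to-end pipeline
and training tests, not a physical light-transport model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image, ImageEnhance

logger = logging.getLogger(__name__)

__all__ = [
    "EggLabel",
    "EggGrade",
    "GRADE_OF",
    "SplitSpec",
    "AugmentSpec",
    "SyntheticEggParams",
    "split_counts",
    "split_dataset",
    "augment_training_set",
    "generate_synthetic_dataset",
    "render_egg",
    "load_image_folder",
    "preprocess",
    "compute_normalization_stats",
]


class EggLabel(Enum):
    QP = 0
    PP = 1
    BYP = 2
    YYP = 3
    IP = 4

    @property
    def grade(self):
        return GRADE_OF[self]


class EggGrade(Enum):
    QP = 0
    SP = 1
    IP = 2


GRADE_OF = {
    EggLabel.QP: EggGrade.QP,
    EggLabel.PP: EggGrade.SP,
    EggLabel.BYP: EggGrade.SP,
    EggLabel.YYP: EggGrade.SP,
    EggLabel.IP: EggGrade.IP,
}


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitSpec:
    """Per-class 7:2:1 split: floor on train and validation, rest to test."""

    ratios: tuple = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must be three values summing to 1")


def split_counts(n, ratios=(0.7, 0.2, 0.1)):
    """(train, validation, test) sizes for one class of ``n`` items."""
    tr = int(np.floor(ratios[0] * n))
    va = int(np.floor(ratios[1] * n))
    return tr, va, n - tr - va


@dataclass
class Split:
    train: list
    val: list
    test: list


def split_dataset(items_by_label, spec: SplitSpec = None):
    """Split a {label: [item, ...]} mapping into train/val/test.

    Each subset is a list of ``(item, label)`` pairs.  Selection order is a
    seeded per-class shuffle; the three subsets partition the input.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    out = Split([], [], [])
    for label, items in items_by_label.items():
        items = list(items)
        if not items:
            raise ValueError(f"class {label} is empty")
        order = rng.permutation(len(items))
        tr, va, _ = split_counts(len(items), spec.ratios)
        for pos, idx in enumerate(order):
            pair = (items[idx], label)
            if pos < tr:
                out.train.append(pair)
            elif pos < tr + va:
                out.val.append(pair)
            else:
                out.test.append(pair)
    return out


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentSpec:
    """Random flips/rotation/contrast/brightness, applied factor-fold.

    Copy 1 of each image is the identity (the raw distribution is kept);
    the remaining ``factor - 1`` copies each apply every enabled operator
    independently with probability ``p``.
    """

    factor: int = 10
    hflip: bool = True
    vflip: bool = True
    rotate_deg: float = 30.0
    contrast: tuple = (0.8, 1.2)
    brightness: tuple = (0.8, 1.2)
    p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("factor must be >= 1")


def _to_pil(img):
    if isinstance(img, Image.Image):
        return img
    return Image.fromarray(np.asarray(img, dtype=np.uint8))


def augment_image(img, rng, spec: AugmentSpec):
    """One random augmented copy of a PIL image."""
    out = img
    if spec.hflip and rng.random() < spec.p:
        out = out.transpose(Image.FLIP_LEFT_RIGHT)
    if spec.vflip and rng.random() < spec.p:
        out = out.transpose(Image.FLIP_TOP_BOTTOM)
    if spec.rotate_deg and rng.random() < spec.p:
        angle = rng.uniform(-spec.rotate_deg, spec.rotate_deg)
        out = out.rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    if spec.contrast and rng.random() < spec.p:
        out = ImageEnhance.Contrast(out).enhance(rng.uniform(*spec.contrast))
    if spec.brightness and rng.random() < spec.p:
        out = ImageEnhance.Brightness(out).enhance(rng.uniform(*spec.brightness))
    return out


def augment_training_set(labeled_images, spec: AugmentSpec = None):
    """Expand [(image, label), ...] to factor x its size, labels preserved."""
    spec = spec or AugmentSpec()
    rng = np.random.default_rng(spec.seed)
    out = []
    for img, label in labeled_images:
        pil = _to_pil(img)
        out.append((pil, label))
        for _ in range(spec.factor - 1):
            out.append((augment_image(pil, rng, spec), label))
    return out


# ---------------------------------------------------------------------------
# synthetic candling images


@dataclass
class ClassAppearance:
    albumen_rgb: tuple          # transmitted color of the translucent body
    albumen_gain: float         # overall translucency (0 = opaque)
    yolk_rgb: tuple = (42, 26, 20)
    yolk_visible: bool = True
    boundary_amplitude: float = 0.02   # radial irregularity of the yolk edge
    rim_rgb: tuple = None       # yellow annulus at the yolk rim (YYP)
    air_chamber: bool = True


@dataclass
class SyntheticEggParams:
    """Rendering parameters of the synthetic candling-image generator."""

    image_size: int = 224
    background_level: float = 12.0
    noise_sigma: float = 4.0
    seed: int = 0
    appearance: dict = field(default_factory=lambda: {
        EggLabel.QP: ClassAppearance((215, 120, 55), 1.0),
        EggLabel.PP: ClassAppearance((170, 158, 88), 0.62),
        EggLabel.BYP: ClassAppearance((215, 120, 55), 1.0,
                                      boundary_amplitude=0.22),
        EggLabel.YYP: ClassAppearance((215, 120, 55), 1.0,
                                      rim_rgb=(225, 195, 60)),
        EggLabel.IP: ClassAppearance((40, 32, 27), 1.0, yolk_visible=False,
                                     air_chamber=False),
    })


def _yolk_radius(theta, base, amplitude, rng):
    """Smooth random radial modulation of the yolk boundary."""
    r = np.full_like(theta, base)
    for k in range(2, 6):
        r += base * amplitude * rng.uniform(0.3, 1.0) * np.sin(
            k * theta + rng.uniform(0, 2 * np.pi)
        )
    return r


def render_egg(label: EggLabel, rng, params: SyntheticEggParams = None):
    """Render one candling image for ``label`` as a uint8 HxWx3 array."""
    params = params or SyntheticEggParams()
    s = params.image_size
    if s <= 0:
        raise ValueError("image size must be positive")
    app = params.appearance[label]
    yy, xx = np.mgrid[0:s, 0:s].astype(float) / s  # unit square
    cx = 0.5 + rng.uniform(-0.03, 0.03)
    cy = 0.52 + rng.uniform(-0.03, 0.03)
    ax = 0.30 * rng.uniform(0.9, 1.1)   # semi-axes of the silhouette
    ay = 0.40 * rng.uniform(0.9, 1.1)
    dx, dy = (xx - cx) / ax, (yy - cy) / ay
    rho2 = dx * dx + dy * dy
    egg = rho2 <= 1.0

    img = np.full((s, s, 3), params.background_level, dtype=float)
    img += rng.normal(0, 2.0, size=(s, s, 1))

    # translucent body: brightest at the center, falling toward the shell
    falloff = np.clip(1.15 - 0.65 * rho2, 0, None)
    body = np.asarray(app.albumen_rgb, dtype=float) * app.albumen_gain
    img[egg] = (falloff[..., None] * body)[egg]

    if app.air_chamber:
        # bright cap at the blunt (top) end where the air cell sits
        cap = (rho2 <= 1.0) & (dy < -0.55)
        img[cap] = np.minimum(img[cap] * 1.45 + 25, 255)

    if app.yolk_visible:
        ycx = cx + rng.uniform(-0.02, 0.02)
        ycy = cy + 0.06 + rng.uniform(-0.02, 0.02)
        theta = np.arctan2(yy - ycy, xx - ycx)
        base_r = 0.16 * rng.uniform(0.9, 1.1)
        r_bound = _yolk_radius(theta, base_r, app.boundary_amplitude, rng)
        dist = np.hypot(xx - ycx, yy - ycy)
        yolk = (dist <= r_bound) & egg
        img[yolk] = np.asarray(app.yolk_rgb, dtype=float)
        if app.rim_rgb is not None:
            rim = (dist > r_bound * 0.78) & yolk
            img[rim] = np.asarray(app.rim_rgb, dtype=float)

    img += rng.normal(0, params.noise_sigma, size=(s, s, 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_synthetic_dataset(params: SyntheticEggParams = None,
                               counts=None, out_dir=None):
    """Render ``counts[label]`` images per class; deterministic under seed.

    Returns [(uint8 image, label), ...].  If ``out_dir`` is given, also
    writes PNGs in a directory-per-class layout.
    """
    params = params or SyntheticEggParams()
    counts = counts or {label: 20 for label in EggLabel}
    rng = np.random.default_rng(params.seed)
    out = []
    for label in EggLabel:
        n = counts.get(label, 0)
        if n < 0:
            raise ValueError("counts must be nonnegative")
        for i in range(n):
            img = render_egg(label, rng, params)
            out.append((img, label))
            if out_dir is not None:
                d = Path(out_dir) / label.name
                d.mkdir(parents=True, exist_ok=True)
                Image.fromarray(img).save(d / f"{label.name}_{i:04d}.png")
    return out


# ---------------------------------------------------------------------------
# loading and preprocessing


def load_image_folder(root):
    """Read a directory-per-class layout into {EggLabel: [uint8 HWC, ...]}.

    Unknown subdirectories are an error naming the five valid labels;
    unreadable files are skipped with a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    valid = {l.name for l in EggLabel}
    out = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if sub.name not in valid:
            raise ValueError(
                f"unknown class directory {sub.name!r}; expected one of "
                f"{sorted(valid)}"
            )
        label = EggLabel[sub.name]
        images = []
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                with Image.open(f) as im:
                    images.append(np.asarray(im.convert("RGB")))
            except Exception as err:  # corrupt file: warn and move on
                warnings.warn(f"skipping unreadable image {f}: {err}")
                logger.warning("skipping unreadable image %s: %s", f, err)
        if not images:
            warnings.warn(f"class directory {sub.name} contains no images")
        out[label] = images
    return out


def preprocess(img, input_size=224, mean=None, std=None):
    """Resize (short side = 8/7 of target), center-crop, normalize -> CHW."""
    pil = _to_pil(img)
    short = min(pil.size)
    scale = int(round(input_size * 8 / 7))
    new = (round(pil.size[0] * scale / short), round(pil.size[1] * scale / short))
    pil = pil.resize(new, Image.BILINEAR)
    left = (pil.size[0] - input_size) // 2
    top = (pil.size[1] - input_size) // 2
    pil = pil.crop((left, top, left + input_size, top + input_size))
    x = np.asarray(pil, dtype=np.float32) / 255.0
    if mean is not None:
        x = (x - np.asarray(mean, dtype=np.float32)) / np.asarray(
            std, dtype=np.float32
        )
    return np.moveaxis(x, -1, 0)  # HWC -> CHW


def compute_normalization_stats(images):
    """Per-channel mean/std of a list of uint8 HWC images (0-1 scale)."""
    acc = np.zeros(3)
    acc2 = np.zeros(3)
    n = 0
    for img in images:
        x = np.asarray(img, dtype=np.float64) / 255.0
        acc += x.reshape(-1, 3).sum(axis=0)
        acc2 += (x.reshape(-1, 3) ** 2).sum(axis=0)
        n += x.shape[0] * x.shape[1]
    mean = acc / n
    std = np.sqrt(np.maximum(acc2 / n - mean**2, 1e-12))
    return mean, std
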