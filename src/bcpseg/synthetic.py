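"""Seedable generator of skin-like lesion images with exact masks.

The generator emulates the data regime of close-up skin patches: square
RGB crops with varied base skin tone, a linear lighting gradient in a
random direction, mild sensor noise, and 0-3 reddish lesions rendered as
randomly perturbed ellipses (radius jitter plus smooth low-frequency
boundary noise). The ground-truth mask is the exact union of the rendered
lesion supports — lesion color is applied only to pixels inside the mask,
so no soft edge can leak foreground outside it.

Also provided: conversion of detection bounding boxes to elliptical
pseudo ground truth (the axis-aligned ellipse inscribed in the box, which
passes through the midpoint of each side) for datasets annotated with
boxes only.

Rasterisation convention: pixel (r, c) covers the unit square
[r, r+1) x [c, c+1) and is tested at its center (r+0.5, c+0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

Interval = tuple[float, float]


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic lesion-image generator.

    Defaults are desk-scale (64 px) for fast tests; 256 px matches the
    patch size used for real acne crops.
    """

    image_size: int = 64
    n_images: int = 20
    lesions_per_image: tuple[int, int] = (0, 3)
    lesion_radius_range: Interval = (4.0, 10.0)
    skin_tone_range: tuple[Interval, Interval, Interval] = (
        (0.45, 0.95), (0.30, 0.80), (0.22, 0.70))
    lighting_gradient_strength: float = 0.25
    lesion_hue_shift_range: tuple[Interval, Interval, Interval] = (
        (0.02, 0.18), (-0.30, -0.06), (-0.30, -0.06))
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ConfigurationError("image_size must be at least 16")
        if self.n_images < 0:
            raise ConfigurationError("n_images must be non-negative")
        lo, hi = self.lesions_per_image
        if not (0 <= lo <= hi):
            raise ConfigurationError(
                f"invalid lesions_per_image range {self.lesions_per_image}")
        rlo, rhi = self.lesion_radius_range
        if not (0 < rlo <= rhi):
            raise ConfigurationError(
                f"invalid lesion_radius_range {self.lesion_radius_range}")
        if rhi * 2 > self.image_size:
            raise ConfigurationError(
                f"lesion radius {rhi} too large for image {self.image_size}")
        for name, ranges in (("skin_tone_range", self.skin_tone_range),
                             ("lesion_hue_shift_range",
                              self.lesion_hue_shift_range)):
            for lo_c, hi_c in ranges:
                if lo_c > hi_c:
                    raise ConfigurationError(f"empty interval in {name}")
        if not 0 <= self.lighting_gradient_strength < 1:
            raise ConfigurationError(
                "lighting_gradient_strength must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, 0-based, half-open."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError(f"degenerate box {self}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"box {self} outside image bounds")

    def validate_within(self, h: int, w: int) -> None:
        if self.x_max > w or self.y_max > h:
            raise ValueError(f"box {self} exceeds image {h}x{w}")


def bbox_to_ellipse_mask(box: BoundingBox,
                         image_size: int | tuple[int, int]) -> np.ndarray:
    """Filled axis-aligned ellipse inscribed in ``box``.

    The ellipse passes through the midpoint of each box side; a pixel is
    foreground when its center satisfies
    ``((x+0.5-cx)/a)^2 + ((y+0.5-cy)/b)^2 <= 1``. A 1-pixel-wide box
    degenerates to a single-pixel mask.
    """
    h, w = ((image_size, image_size) if isinstance(image_size, int)
            else image_size)
    box.validate_within(h, w)
    cx = (box.x_min + box.x_max) / 2.0
    cy = (box.y_min + box.y_max) / 2.0
    a = (box.x_max - box.x_min) / 2.0
    b = (box.y_max - box.y_min) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    d = (((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / b) ** 2)
    return (d <= 1.0).astype(np.uint8)


def _render_lesion_mask(size: int, rng: np.random.Generator,
                        radius_range: Interval) -> np.ndarray:
    """Support of one perturbed-ellipse lesion (exact, by pixel center).

    The boundary radius is modulated with a few low-frequency harmonics so
    lesions are irregular but simply connected.
    """
    r_base = rng.uniform(*radius_range)
    aspect = rng.uniform(0.6, 1.0)
    theta = rng.uniform(0, 2 * np.pi)
    margin = r_base + 1
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    n_harm = 3
    amps = rng.uniform(0.0, 0.15, size=n_harm)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)

    yy, xx = np.mgrid[0:size, 0:size]
    dy = (yy + 0.5) - cy
    dx = (xx + 0.5) - cx
    # rotate into the ellipse frame, squash the minor axis
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / aspect
    rad = np.hypot(u, v)
    phi = np.arctan2(v, u)
    wobble = np.ones_like(phi)
    for k in range(n_harm):
        wobble += amps[k] * np.sin((k + 2) * phi + phases[k])
    return (rad <= r_base * wobble).astype(np.uint8)


def _render_image(cfg: SynthConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) sample; the mask is the exact lesion union."""
    size = cfg.image_size
    base = np.array([rng.uniform(lo, hi) for lo, hi in cfg.skin_tone_range])
    img = np.broadcast_to(base, (size, size, 3)).copy()

    # linear luminance gradient along a random direction
    ang = rng.uniform(0, 2 * np.pi)
    s = cfg.lighting_gradient_strength
    yy, xx = np.mgrid[0:size, 0:size]
    t = ((xx * np.cos(ang) + yy * np.sin(ang))
         / (size * max(abs(np.cos(ang)) + abs(np.sin(ang)), 1e-9)))
    t = (t - t.min()) / max(t.max() - t.min(), 1e-9)
    img *= (1.0 + s * (2.0 * t - 1.0))[..., None]

    n_lesions = int(rng.integers(cfg.lesions_per_image[0],
                                 cfg.lesions_per_image[1] + 1))
    mask = np.zeros((size, size), dtype=np.uint8)
    for _ in range(n_lesions):
        support = _render_lesion_mask(size, rng, cfg.lesion_radius_range)
        shift = np.array([rng.uniform(lo, hi)
                          for lo, hi in cfg.lesion_hue_shift_range])
        # darker toward the lesion interior for a weak 3-d impression
        sel = support.astype(bool)
        depth = rng.uniform(0.6, 1.0)
        img[sel] = img[sel] + depth * shift
        mask |= support

    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), mask


@dataclass
class DatasetBundle:
    """Output of :func:`generate_dataset`."""

    labeled: list[tuple[np.ndarray, np.ndarray]]
    unlabeled: list[np.ndarray]
    val: list[tuple[np.ndarray, np.ndarray]]
    manifest: dict = field(default_factory=dict)


def generate_dataset(cfg: SynthConfig,
                     label_ratio: float = 0.5,
                     val_fraction: float = 0.0,
                     out_dir: str | Path | None = None) -> DatasetBundle:
    """Generate ``cfg.n_images`` samples and partition them.

    The first ``round(val_fraction * n)`` images (after a seeded shuffle)
    become the validation split; of the remaining training images,
    ``round(label_ratio * n_train)`` keep their masks (labeled subset) and
    the rest are stripped to images only (unlabeled subset). Identical
    configs (including seed) give bit-identical output. When ``out_dir``
    is set, images/masks are written as 8-bit PNG plus a JSON manifest.
    """
    if not 0.0 <= label_ratio <= 1.0:
        raise ConfigurationError("label_ratio must be in [0, 1]")
    if not 0.0 <= val_fraction < 1.0:
        raise ConfigurationError("val_fraction must be in [0, 1)")
    rng = np.random.default_rng(cfg.seed)
    samples = [_render_image(cfg, rng) for _ in range(cfg.n_images)]

    order = rng.permutation(cfg.n_images)
    n_val = int(round(val_fraction * cfg.n_images))
    n_train = cfg.n_images - n_val
    n_labeled = int(round(label_ratio * n_train))
    val_idx = order[:n_val]
    lab_idx = order[n_val:n_val + n_labeled]
    unl_idx = order[n_val + n_labeled:]

    roles = {}
    for k in val_idx:
        roles[int(k)] = "val"
    for k in lab_idx:
        roles[int(k)] = "labeled"
    for k in unl_idx:
        roles[int(k)] = "unlabeled"

    bundle = DatasetBundle(
        labeled=[samples[k] for k in lab_idx],
        unlabeled=[samples[k][0] for k in unl_idx],
        val=[samples[k] for k in val_idx],
        manifest={
            "seed": cfg.seed,
            "image_size": cfg.image_size,
            "n_images": cfg.n_images,
            "label_ratio": label_ratio,
            "val_fraction": val_fraction,
            "items": [{"index": k, "role": roles[k],
                       "image": f"img_{k:05d}.png",
                       "mask": (f"mask_{k:05d}.png"
                                if roles[k] != "unlabeled" else None)}
                      for k in range(cfg.n_images)],
        })

    if out_dir is not None:
        _write_pngs(samples, bundle.manifest, Path(out_dir))
    return bundle


def _write_pngs(samples, manifest: dict, out_dir: Path) -> None:
    from PIL import Image

    out_dir.mkdir(parents=True, exist_ok=True)
    for item in manifest["items"]:
        img, mask = samples[item["index"]]
        arr = (img * 255.0 + 0.5).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(out_dir / item["image"])
        if item["mask"] is not None:
            Image.fromarray((mask * 255).astype(np.uint8),
                            mode="L").save(out_dir / item["mask"])
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_dataset(manifest_path: str | Path) -> DatasetBundle:
    """Read a PNG dataset written by :func:`generate_dataset` (masks are
    reconstructed from {0, 255} grayscale)."""
    from PIL import Image

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    labeled, unlabeled, val = [], [], []
    for item in manifest["items"]:
        img = np.asarray(Image.open(root / item["image"]),
                         dtype=np.float32) / 255.0
        mask = None
        if item["mask"] is not None:
            mask = (np.asarray(Image.open(root / item["mask"])) > 127)
            mask = mask.astype(np.uint8)
        if item["role"] == "labeled":
            labeled.append((img, mask))
        elif item["role"] == "val":
            val.append((img, mask))
        else:
            unlabeled.append(img)
    return DatasetBundle(labeled, unlabeled, val, manifest)
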