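"""The three augmentation regimes and class-balancing oversampling.

Three regimes are supported, mirroring common practice for imbalanced
fine-grained collections:

* ``standard`` — a random subset (at least one) of six operators, each
  with random parameters: horizontal flip, vertical flip, colour
  channel shift, brightness/contrast alteration, additive Gaussian
  noise, Gaussian blur, applied in that fixed canonical order
  (geometric -> photometric -> noise -> blur).
* ``central_crop`` — one extra record per training image holding its
  central patch (80% of each linear dimension by default), cropped
  BEFORE the resize so detail is preserved; includes ``standard``.
* ``multiscale_crop`` — three extra records per training image, central
  crops of random size uniform in [50%, 80%]; includes ``standard``.

Balancing augments the least represented finest-level classes until
every class matches the most represented one, so e.g. 1010 classes
with a 350-sample maximum yield a 353500-record training set.
Augmented records are lazy: they store (source image, transform seed,
crop fraction) and are materialised at load time, which keeps the
record-count contract without writing hundreds of thousands of files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataio import (
    DatasetManifest,
    SampleRecord,
    load_image_raw,
    resize_bilinear,
)

__all__ = [
    "AugmentPolicy",
    "standard_augment",
    "central_crop",
    "multiscale_crops",
    "balance_dataset",
    "materialize_image",
]

MODES = ("none", "standard", "central_crop", "multiscale_crop")


@dataclass(frozen=True)
class AugmentPolicy:
    """Operator inclusion probabilities and parameter ranges.

    Ranges are uniform; the defaults keep every operator mild enough
    that class identity is preserved.  ``central_fraction`` and
    ``multiscale_range`` are linear-dimension fractions.
    """

    mode: str = "standard"
    seed: int = 0
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_channel_shift: float = 0.5
    p_brightness_contrast: float = 0.5
    p_noise: float = 0.5
    p_blur: float = 0.5
    channel_shift_mag: float = 0.1
    brightness_delta_range: tuple[float, float] = (-0.2, 0.2)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    noise_sigma_range: tuple[float, float] = (0.0, 0.05)
    blur_sigma_range: tuple[float, float] = (0.0, 1.5)
    central_fraction: float = 0.8
    multiscale_range: tuple[float, float] = (0.5, 0.8)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 < self.central_fraction <= 1.0:
            raise ValueError("central_fraction must lie in (0, 1]")
        lo, hi = self.multiscale_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("multiscale_range must lie in (0, 1]")


def standard_augment(
    image: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator
) -> np.ndarray:
    """Apply a random non-empty subset of the six standard operators.

    Operators run in canonical order (flips, channel shift,
    brightness/contrast, noise, blur); each drawn parameter comes from
    the policy's ranges.  Output is clipped to [0, 1], same shape.
    """
    probs = np.array(
        [
            policy.p_hflip,
            policy.p_vflip,
            policy.p_channel_shift,
            policy.p_brightness_contrast,
            policy.p_noise,
            policy.p_blur,
        ]
    )
    gates = rng.uniform(size=6) < probs
    if not gates.any():
        forced = int(rng.integers(0, 6))
        gates[forced] = True

    out = image.astype(np.float64, copy=True)
    if gates[0]:
        out = out[:, ::-1, :]
    if gates[1]:
        out = out[::-1, :, :]
    if gates[2]:
        shift = rng.uniform(
            -policy.channel_shift_mag, policy.channel_shift_mag, size=3
        )
        out = out + shift[None, None, :]
    if gates[3]:
        delta = rng.uniform(*policy.brightness_delta_range)
        factor = rng.uniform(*policy.contrast_range)
        out = (out - 0.5) * factor + 0.5 + delta
    if gates[4]:
        sigma = rng.uniform(*policy.noise_sigma_range)
        out = out + sigma * rng.normal(size=out.shape)
    if gates[5]:
        sigma = rng.uniform(*policy.blur_sigma_range)
        if sigma > 0:
            blurred = np.empty_like(out)
            for ch in range(out.shape[2]):
                blurred[..., ch] = gaussian_filter(out[..., ch], sigma=sigma)
            out = blurred
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)


def central_crop(image: np.ndarray, fraction: float) -> np.ndarray:
    """Centered window of side ``round(fraction * side)`` per dimension.

    Offsets are ``floor((1 - fraction) * side / 2)``.  Applied to the
    original-resolution image, before any resize.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"crop fraction must lie in (0, 1], got {fraction}")
    h, w = image.shape[:2]
    new_h = int(math.floor(fraction * h + 0.5))
    new_w = int(math.floor(fraction * w + 0.5))
    if new_h < 1 or new_w < 1:
        raise ValueError(
            f"crop fraction {fraction} yields a zero-size window on {h}x{w}"
        )
    # floor((1-fraction)*side/2), computed in integers to dodge float error
    r0 = (h - new_h) // 2
    c0 = (w - new_w) // 2
    return image[r0 : r0 + new_h, c0 : c0 + new_w].copy()


def multiscale_crops(
    image: np.ndarray,
    rng: np.random.Generator,
    frac_range: tuple[float, float] = (0.5, 0.8),
) -> list[np.ndarray]:
    """Three central crops with independent fractions uniform in the range."""
    lo, hi = frac_range
    fractions = rng.uniform(lo, hi, size=3)
    return [central_crop(image, float(f)) for f in fractions]


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def _crop_records(
    records: list[SampleRecord], policy: AugmentPolicy, rng: np.random.Generator
) -> list[SampleRecord]:
    """Extra crop records per train source, per the crop regimes."""
    extra: list[SampleRecord] = []
    for rec in records:
        if rec.split != "train" or rec.is_augmented:
            continue
        if policy.mode == "central_crop":
            fractions = [policy.central_fraction]
        else:  # multiscale_crop
            lo, hi = policy.multiscale_range
            fractions = [float(f) for f in rng.uniform(lo, hi, size=3)]
        for f in fractions:
            extra.append(
                replace(
                    rec,
                    source_path=rec.image_path,
                    transform_seed=int(rng.integers(0, 2**31)),
                    crop_fraction=f,
                )
            )
    return extra


def balance_dataset(
    manifest: DatasetManifest, policy: AugmentPolicy
) -> DatasetManifest:
    """Equalize every finest-level train class to the maximum class count.

    Crop regimes first ADD their crop records (one per source for
    central, three for multiscale); then under-represented classes gain
    augmented copies of their own train records (round-robin over
    sources, each tagged with a fresh transform seed) until all counts
    equal the post-crop maximum.  Originals are retained unchanged and
    the test split is never touched.
    """
    if policy.mode == "none":
        return manifest
    train = manifest.split_records("train")
    if not train:
        raise ValueError("train split is empty; nothing to balance")
    rng = np.random.default_rng(np.random.SeedSequence(policy.seed))

    records = list(manifest.records)
    if policy.mode in ("central_crop", "multiscale_crop"):
        records = records + _crop_records(records, policy, rng)

    by_class: dict[int, list[SampleRecord]] = {}
    for rec in records:
        if rec.split == "train":
            by_class.setdefault(rec.labels[-1], []).append(rec)
    max_count = max(len(v) for v in by_class.values())

    added: list[SampleRecord] = []
    for cls in sorted(by_class):
        sources = by_class[cls]
        deficit = max_count - len(sources)
        for i in range(deficit):
            src = sources[i % len(sources)]
            added.append(
                replace(
                    src,
                    source_path=src.source_path or src.image_path,
                    transform_seed=int(rng.integers(0, 2**31)),
                )
            )
    return DatasetManifest(
        records=records + added, tree=manifest.tree, image_root=manifest.image_root
    )


def materialize_image(
    record: SampleRecord,
    policy: AugmentPolicy,
    resolution: int,
    image_root: str = ".",
) -> np.ndarray:
    """Load one (possibly augmented) record at the target resolution.

    Pipeline: decode source -> central crop (original resolution) ->
    corner-aligned bilinear resize -> standard operators seeded by the
    record's transform seed.
    """
    from pathlib import Path

    path = Path(image_root) / (record.source_path or record.image_path)
    img = load_image_raw(path)
    if record.crop_fraction is not None:
        img = central_crop(img, record.crop_fraction)
    img = resize_bilinear(img, resolution, resolution)
    if record.transform_seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence(record.transform_seed))
        img = standard_augment(img, policy, rng)
    return img
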