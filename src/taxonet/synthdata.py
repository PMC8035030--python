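"""Procedural hierarchical image benchmark generator.

Produces fully synthetic datasets whose visual attributes are nested by
taxonomic rank, so that the hierarchy is real signal and not an
annotation convention:

* the level-0 (coarsest) ancestor sets the background hue band,
* an intermediate ancestor sets the subject silhouette (from a fixed
  shape alphabet), the fill texture and the stroke pattern,
* the leaf sets a small distinctive marking at the subject's centre.

Coarse attributes therefore occupy many more pixels than fine ones,
mirroring real wildlife imagery where kingdom-level appearance is easy
and congeneric species differ in small details.  The generator also
emulates the standard pathologies of field photographs: strong class
imbalance, subjects covering anything from the whole frame down to a
small patch, background clutter, additive noise and blur.

All randomness flows through counter-based streams derived from one
seed (``SeedSequence(seed, spawn_key=(leaf, sample))``), so generation
order never changes content, and two renders that share a stream differ
only through rank attributes.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import binary_erosion, gaussian_filter

from .dataio import DatasetManifest, SampleRecord, write_manifest_csv
from .taxonomy import TaxonomyTree, ancestor_path, build_taxonomy, taxonomy_to_json

__all__ = [
    "SyntheticSpec",
    "make_synthetic_taxonomy",
    "make_shaped_taxonomy",
    "render_sample",
    "generate_dataset",
    "skewed_counts",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``branching[i]`` is the number of children per level-``i-1`` parent
    (so level sizes are the cumulative products).  ``samples_per_leaf``
    may be a single int (balanced) or one count per leaf (imbalanced).
    ``subject_scale_range`` is the subject's side as a fraction of the
    frame; the default spans whole-frame subjects down to small patches.
    """

    branching: tuple[int, ...] = (3, 4)
    samples_per_leaf: int | tuple[int, ...] = 20
    image_size: int = 48
    subject_scale_range: tuple[float, float] = (0.3, 1.0)
    noise_sigma: float = 0.05
    blur_prob: float = 0.25
    blur_sigma: float = 1.0
    clutter_blobs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.branching or any(b < 1 for b in self.branching):
            raise ValueError(f"branching must be positive ints, got {self.branching}")
        lo, hi = self.subject_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("subject_scale_range must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.blur_prob <= 1.0:
            raise ValueError("blur_prob must be a probability")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")

    @property
    def level_sizes(self) -> list[int]:
        sizes, prod = [], 1
        for b in self.branching:
            prod *= b
            sizes.append(prod)
        return sizes

    def leaf_counts(self) -> list[int]:
        n_leaves = self.level_sizes[-1]
        if isinstance(self.samples_per_leaf, int):
            return [self.samples_per_leaf] * n_leaves
        counts = list(self.samples_per_leaf)
        if len(counts) != n_leaves:
            raise ValueError(
                f"samples_per_leaf has {len(counts)} entries for {n_leaves} leaves"
            )
        return counts


def make_synthetic_taxonomy(
    spec: SyntheticSpec, level_names: Sequence[str] | None = None
) -> TaxonomyTree:
    """A complete tree with ``branching[i]`` children per parent.

    Node names encode the path with zero-padded indices, so the
    lexicographic id assignment of :func:`build_taxonomy` coincides with
    mixed-radix leaf order.
    """
    branching = spec.branching
    n_levels = len(branching)
    if level_names is None:
        level_names = [f"level{i}" for i in range(n_levels)]
    records = []
    n_leaves = spec.level_sizes[-1]
    for leaf in range(n_leaves):
        digits = []
        rem = leaf
        for b in reversed(branching):
            digits.append(rem % b)
            rem //= b
        digits.reverse()
        path, name = [], ""
        for d in digits:
            name = f"{name}.{d:03d}" if name else f"t{d:03d}"
            path.append(name)
        records.append(tuple(path))
    return build_taxonomy(records, level_names)


def make_shaped_taxonomy(
    level_sizes: Sequence[int], level_names: Sequence[str] | None = None
) -> TaxonomyTree:
    """A tree with exactly the given per-level category counts.

    Sizes must be non-decreasing.  The category at position ``c`` of
    level ``i`` is parented to ``c mod level_sizes[i-1]``, which keeps
    every parent populated.  Useful for reproducing a published
    taxonomy shape (e.g. 3/4/9/34/57/72/1010) without its labels.
    """
    sizes = list(level_sizes)
    if any(a > b for a, b in zip(sizes, sizes[1:])):
        raise ValueError("level sizes must be non-decreasing")
    if level_names is None:
        level_names = [f"level{i}" for i in range(len(sizes))]
    records = []
    for leaf in range(sizes[-1]):
        ids = [leaf]
        for size in reversed(sizes[:-1]):
            ids.append(ids[-1] % size)
        ids.reverse()
        records.append(
            tuple(f"{level_names[i]}_{c:04d}" for i, c in enumerate(ids))
        )
    return build_taxonomy(records, level_names)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _hsv(h: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb(h % 1.0, s, v))


def _shape_mask(shape_id: int, side: int) -> np.ndarray:
    """Boolean silhouette from the fixed shape alphabet."""
    ax = (np.arange(side) + 0.5) / side - 0.5
    v, u = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(u, v)
    alphabet = [
        lambda: r <= 0.45,                                   # disc
        lambda: np.maximum(np.abs(u), np.abs(v)) <= 0.42,    # square
        lambda: (np.abs(u) <= (v + 0.45) / 2.0) & (v <= 0.45),  # triangle
        lambda: np.abs(u) + np.abs(v) <= 0.48,               # diamond
        lambda: ((np.abs(u) <= 0.14) | (np.abs(v) <= 0.14))
        & (np.maximum(np.abs(u), np.abs(v)) <= 0.45),        # cross
        lambda: (r <= 0.45) & (r >= 0.24),                   # ring
    ]
    return alphabet[shape_id % len(alphabet)]()


def _attr_ids(tree: TaxonomyTree, leaf_id: int) -> dict[str, int]:
    """Map rank-path entries to visual-attribute slots.

    The leaf always owns only the marking; the coarsest ancestor owns
    the background; silhouette/texture/stroke come from intermediate
    ancestors (clamped for shallow trees so clades share coarse looks).
    """
    path = ancestor_path(tree, leaf_id)
    top = max(0, tree.n_levels - 2)  # deepest non-leaf level
    return {
        "background": path[0],
        "shape": path[min(1, top)],
        "texture": path[min(2, top)],
        "stroke": path[min(3, top)],
        "marking": path[-1],
    }


def render_sample(
    tree: TaxonomyTree,
    leaf_id: int,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    with_meta: bool = False,
):
    """Render one image for a leaf category.

    All stochastic draws (subject scale and position, clutter, blur
    coin, noise field) are independent of the leaf identity, so two
    renders from identical generator states for leaves sharing all
    ancestors differ only inside the leaf-marking region.
    """
    S = spec.image_size
    attrs = _attr_ids(tree, leaf_id)

    # -- stochastic draws, fixed order ------------------------------------
    lo, hi = spec.subject_scale_range
    scale = rng.uniform(lo, hi)
    side = max(4, int(math.floor(scale * S + 0.5)))
    side = min(side, S)
    r0 = int(rng.integers(0, S - side + 1))
    c0 = int(rng.integers(0, S - side + 1))
    blob_params = rng.uniform(size=(spec.clutter_blobs, 5))
    blur_coin = rng.uniform()
    noise = rng.normal(size=(S, S, 3))

    # -- background: hue band of the coarsest ancestor + clutter ----------
    bg_hue = (0.11 + 0.37 * attrs["background"]) % 1.0
    base = _hsv(bg_hue, 0.45, 0.50)
    img = np.empty((S, S, 3))
    grad = np.linspace(-0.07, 0.07, S)[:, None, None]
    img[:] = base[None, None, :] + grad
    yy, xx = np.meshgrid(np.arange(S), np.arange(S), indexing="ij")
    for cy, cx, rad, dh, dv in blob_params:
        cy, cx = cy * S, cx * S
        radius = (0.03 + 0.09 * rad) * S
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        color = _hsv(bg_hue + (dh - 0.5) * 0.16, 0.5, 0.35 + 0.4 * dv)
        img[blob] = color

    # -- subject: silhouette, texture fill, stroke ------------------------
    mask = _shape_mask(attrs["shape"], side)
    ax = (np.arange(side) + 0.5) / side - 0.5
    sv, su = np.meshgrid(ax, ax, indexing="ij")
    theta = attrs["texture"] * math.pi / 5.0
    freq = 3 + attrs["texture"] % 4
    wave = np.cos(2 * math.pi * freq * (su * math.cos(theta) + sv * math.sin(theta)))
    fill_hue = (bg_hue + 0.5) % 1.0
    fill_v = 0.72 + 0.18 * wave
    tile = img[r0 : r0 + side, c0 : c0 + side].copy()
    fill = np.stack(
        [
            np.full_like(fill_v, 0.0),
            np.full_like(fill_v, 0.0),
            np.full_like(fill_v, 0.0),
        ],
        axis=-1,
    )
    base_fill = _hsv(fill_hue, 0.85, 1.0)
    for ch in range(3):
        fill[..., ch] = base_fill[ch] * fill_v
    tile[mask] = fill[mask]

    edge = mask & ~binary_erosion(mask, iterations=max(1, side // 16))
    ang = np.arctan2(sv, su)
    dashes = 3 + attrs["stroke"] % 5
    dash_keep = (
        np.floor((ang + math.pi) / (2 * math.pi) * 2 * dashes).astype(int) % 2 == 0
    )
    if attrs["stroke"] % 2 == 0:
        dash_keep = np.ones_like(dash_keep)
    stroke_color = 0.05 if attrs["stroke"] % 3 else 0.95
    tile[edge & dash_keep] = stroke_color

    # -- leaf marking: small 2x2-checker patch at the subject centre ------
    m = max(2, int(math.floor(0.3 * side + 0.5)))
    mr = (side - m) // 2
    hue_a = (0.05 + 0.389 * attrs["marking"]) % 1.0
    hue_b = (hue_a + 0.5) % 1.0
    half = m // 2
    patch = np.empty((m, m, 3))
    patch[:] = _hsv(hue_a, 0.95, 0.95)
    if attrs["marking"] % 2 == 0:
        patch[:half, :half] = _hsv(hue_b, 0.95, 0.9)
        patch[half:, half:] = _hsv(hue_b, 0.95, 0.9)
    else:
        patch[:half, half:] = _hsv(hue_b, 0.95, 0.9)
        patch[half:, :half] = _hsv(hue_b, 0.95, 0.9)
    tile[mr : mr + m, mr : mr + m] = patch
    img[r0 : r0 + side, c0 : c0 + side] = tile

    # -- degradations ------------------------------------------------------
    if blur_coin < spec.blur_prob:
        for ch in range(3):
            img[..., ch] = gaussian_filter(img[..., ch], sigma=spec.blur_sigma)
    img = img + spec.noise_sigma * noise
    img = np.clip(img, 0.0, 1.0)

    if with_meta:
        meta = {
            "subject_bbox": (r0, c0, side, side),
            "marking_bbox": (r0 + mr, c0 + mr, m, m),
            "attrs": attrs,
        }
        return img, meta
    return img


def sample_rng(seed: int, leaf_id: int, sample_index: int) -> np.random.Generator:
    """The counter-based per-sample stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(leaf_id, sample_index))
    )


def generate_dataset(
    spec: SyntheticSpec,
    train_fraction: float = 0.8,
    out_dir: str | Path = "synthetic",
    level_names: Sequence[str] | None = None,
) -> DatasetManifest:
    """Render a full dataset to disk (PNGs + manifest CSV + taxonomy JSON).

    Per-leaf counts honour ``spec.samples_per_leaf``; the train/test
    split is stratified by leaf with ``round(train_fraction * n)`` train
    samples per leaf.  Same spec + seed gives byte-identical output.
    """
    if not 0.0 <= train_fraction <= 1.0:
        raise ValueError("train_fraction must be in [0, 1]")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    tree = make_synthetic_taxonomy(spec, level_names)
    counts = spec.leaf_counts()

    records = []
    for leaf in range(tree.n_leaves):
        labels = tuple(ancestor_path(tree, leaf))
        n = counts[leaf]
        n_train = int(math.floor(n * train_fraction + 0.5))
        for j in range(n):
            rng = sample_rng(spec.seed, leaf, j)
            img = render_sample(tree, leaf, spec, rng)
            rel = f"images/leaf{leaf:04d}_{j:04d}.png"
            arr8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr8).save(out_dir / rel)
            records.append(
                SampleRecord(
                    image_path=rel,
                    labels=labels,
                    split="train" if j < n_train else "test",
                )
            )
    manifest = DatasetManifest(records=records, tree=tree, image_root=str(out_dir))
    write_manifest_csv(manifest, out_dir / "manifest.csv")
    (out_dir / "taxonomy.json").write_text(taxonomy_to_json(tree))
    return manifest


def skewed_counts(
    n_leaves: int, max_count: int, min_count: int = 1
) -> list[int]:
    """A deterministic long-tail count profile: geometric decay from
    ``max_count`` down to ``min_count`` across leaves (strong imbalance,
    as in crowd-sourced wildlife collections)."""
    if n_leaves == 1:
        return [max_count]
    ratio = (min_count / max_count) ** (1.0 / (n_leaves - 1))
    return [
        max(min_count, int(round(max_count * ratio**i))) for i in range(n_leaves)
    ]
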