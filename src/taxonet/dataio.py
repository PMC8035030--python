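"""Dataset manifests, the iNaturalist-competition annotation dialect, and
image loading.

All images flow through one pixel convention: RGB, channel-last,
float values in [0, 1].  Resizing is corner-aligned bilinear, applied
anisotropically so any input lands on the square network input.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import map_coordinates

from .taxonomy import TaxonomyTree, build_taxonomy, TaxonomyError

__all__ = [
    "SampleRecord",
    "DatasetManifest",
    "SchemaError",
    "ReferentialError",
    "read_inat_annotations",
    "read_manifest_csv",
    "write_manifest_csv",
    "load_image",
    "load_image_raw",
    "resize_bilinear",
]

SPLITS = ("train", "test")


class SchemaError(ValueError):
    """Annotation file lacks a required field."""


class ReferentialError(ValueError):
    """Annotation references an unknown image or category id."""


@dataclass(frozen=True)
class SampleRecord:
    """One image reference plus its per-rank label vector.

    ``source_path``/``transform_seed``/``crop_fraction`` are set only on
    augmented records: the image is then materialised lazily from the
    source at load time (see :mod:`taxonet.augment`).
    """

    image_path: str
    labels: tuple[int, ...]
    split: str
    source_path: str | None = None
    transform_seed: int | None = None
    crop_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")

    @property
    def is_augmented(self) -> bool:
        return self.source_path is not None or self.crop_fraction is not None


@dataclass
class DatasetManifest:
    """A split-tagged record collection plus its taxonomy."""

    records: list[SampleRecord]
    tree: TaxonomyTree
    image_root: str = "."

    def __post_init__(self) -> None:
        sizes = self.tree.level_sizes
        for rec in self.records:
            if len(rec.labels) != self.tree.n_levels:
                raise TaxonomyError(
                    f"record {rec.image_path}: {len(rec.labels)} labels for "
                    f"{self.tree.n_levels}-level taxonomy"
                )
            for lvl, c in enumerate(rec.labels):
                if not 0 <= c < sizes[lvl]:
                    raise TaxonomyError(
                        f"record {rec.image_path}: label {c} out of range at "
                        f"level {lvl}"
                    )

    def split_records(self, split: str) -> list[SampleRecord]:
        return [r for r in self.records if r.split == split]

    @property
    def class_counts(self) -> np.ndarray:
        """Histogram of the finest-level class over the train split."""
        counts = np.zeros(self.tree.n_leaves, dtype=int)
        for rec in self.records:
            if rec.split == "train":
                counts[rec.labels[-1]] += 1
        return counts

    def resolve(self, rec: SampleRecord) -> Path:
        return Path(self.image_root) / rec.image_path


def subsample_train(
    manifest: DatasetManifest, per_leaf_counts: Sequence[int]
) -> DatasetManifest:
    """Thin the train split to a per-leaf count profile (first records
    kept, deterministic); the test split is untouched.

    Used to impose a long-tail class profile on a balanced dataset
    while keeping a balanced evaluation split.
    """
    if len(per_leaf_counts) != manifest.tree.n_leaves:
        raise ValueError("need one count per leaf")
    seen = [0] * manifest.tree.n_leaves
    kept = []
    for rec in manifest.records:
        if rec.split != "train":
            kept.append(rec)
            continue
        leaf = rec.labels[-1]
        if seen[leaf] < per_leaf_counts[leaf]:
            kept.append(rec)
            seen[leaf] += 1
    return DatasetManifest(
        records=kept, tree=manifest.tree, image_root=manifest.image_root
    )


# ---------------------------------------------------------------------------
# iNaturalist competition annotation dialect (COCO-style JSON)
# ---------------------------------------------------------------------------

_INAT_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "name")
_INAT_LEVEL_NAMES = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)


def read_inat_annotations(
    annotation_file: str | Path,
    image_root: str | Path = ".",
    split: str = "train",
) -> DatasetManifest:
    """Parse a competition-style annotation file into a manifest.

    Expected dialect: a JSON object with ``images`` (id, file_name),
    ``annotations`` (image_id, category_id) and ``categories`` carrying
    the full rank path (kingdom, phylum, class, order, family, genus,
    name).  One record is produced per annotation; the taxonomy is built
    from the categories' rank paths.
    """
    with open(annotation_file) as fh:
        data = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in data:
            raise SchemaError(f"annotation file lacks {key!r}")

    cat_paths: dict[int, tuple[str, ...]] = {}
    for cat in data["categories"]:
        missing = [r for r in _INAT_RANKS if r not in cat]
        if missing:
            raise SchemaError(
                f"category {cat.get('id')}: missing rank field(s) {missing}"
            )
        cat_paths[cat["id"]] = tuple(str(cat[r]) for r in _INAT_RANKS)

    images = {img["id"]: img["file_name"] for img in data["images"]}
    tree = build_taxonomy(cat_paths.values(), _INAT_LEVEL_NAMES)

    records = []
    for ann in data["annotations"]:
        img_id, cat_id = ann["image_id"], ann["category_id"]
        if img_id not in images:
            raise ReferentialError(f"annotation references unknown image id {img_id}")
        if cat_id not in cat_paths:
            raise ReferentialError(
                f"annotation references unknown category id {cat_id}"
            )
        path = cat_paths[cat_id]
        labels = tuple(tree.id_of(lvl, nm) for lvl, nm in enumerate(path))
        records.append(
            SampleRecord(image_path=images[img_id], labels=labels, split=split)
        )
    return DatasetManifest(records=records, tree=tree, image_root=str(image_root))


# ---------------------------------------------------------------------------
# Manifest CSV
# ---------------------------------------------------------------------------

def write_manifest_csv(manifest: DatasetManifest, path: str | Path) -> None:
    """Write records as CSV: path, split, one display name per level,
    plus augmentation provenance columns."""
    tree = manifest.tree
    header = (
        ["path", "split"]
        + [f"label_level{i}" for i in range(tree.n_levels)]
        + ["source_path", "transform_seed", "crop_fraction"]
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(header)
        for rec in manifest.records:
            writer.writerow(
                [rec.image_path, rec.split]
                + [tree.name_of(i, c) for i, c in enumerate(rec.labels)]
                + [
                    rec.source_path or "",
                    "" if rec.transform_seed is None else rec.transform_seed,
                    "" if rec.crop_fraction is None else repr(rec.crop_fraction),
                ]
            )


def read_manifest_csv(
    path: str | Path, image_root: str | Path | None = None
) -> DatasetManifest:
    """Read a manifest CSV back; inverse of :func:`write_manifest_csv`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        label_cols = [h for h in header if h.startswith("label_level")]
        n_levels = len(label_cols)
        if header[:2] != ["path", "split"] or n_levels == 0:
            raise SchemaError(f"{path}: unrecognized manifest header {header}")
        has_prov = header[2 + n_levels :] == [
            "source_path", "transform_seed", "crop_fraction",
        ]
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}"
                )
            rows.append(row)

    level_names = tuple(f"level{i}" for i in range(n_levels))
    name_paths = [tuple(row[2 : 2 + n_levels]) for row in rows]
    if name_paths:
        tree = build_taxonomy(name_paths, level_names)
    else:
        # header-only file: empty manifest over an empty taxonomy is not
        # representable; use a 0-leaf placeholder tree
        tree = build_taxonomy([("__none__",) * n_levels], level_names)
        return DatasetManifest(records=[], tree=tree,
                               image_root=str(image_root or Path(path).parent))

    records = []
    for row, names in zip(rows, name_paths):
        labels = tuple(tree.id_of(i, nm) for i, nm in enumerate(names))
        src = seed = frac = None
        if has_prov:
            src = row[2 + n_levels] or None
            seed = int(row[3 + n_levels]) if row[3 + n_levels] else None
            frac = float(row[4 + n_levels]) if row[4 + n_levels] else None
        records.append(
            SampleRecord(
                image_path=row[0], labels=labels, split=row[1],
                source_path=src, transform_seed=seed, crop_fraction=frac,
            )
        )
    return DatasetManifest(
        records=records, tree=tree,
        image_root=str(image_root or Path(path).parent),
    )


# ---------------------------------------------------------------------------
# Image loading
# ---------------------------------------------------------------------------

def resize_bilinear(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Corner-aligned bilinear resize of an HxWxC float image.

    Sample positions are ``linspace(0, in-1, out)`` per axis, so the four
    corner pixels of the input are reproduced exactly in the output.
    """
    h, w = image.shape[:2]
    if (h, w) == (out_h, out_w):
        return image.copy()
    rows = np.linspace(0.0, h - 1.0, out_h) if out_h > 1 else np.array([(h - 1) / 2])
    cols = np.linspace(0.0, w - 1.0, out_w) if out_w > 1 else np.array([(w - 1) / 2])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((out_h, out_w, image.shape[2]), dtype=np.float64)
    for ch in range(image.shape[2]):
        out[..., ch] = map_coordinates(
            image[..., ch], [rr, cc], order=1, mode="nearest"
        )
    return out


def load_image_raw(path: str | Path) -> np.ndarray:
    """Decode a PNG/JPEG into an HxWx3 float array in [0, 1].

    Grayscale inputs are replicated across the three channels.
    """
    try:
        with Image.open(path) as img:
            img = img.convert("RGB")
            arr = np.asarray(img, dtype=np.float64) / 255.0
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return arr


def load_image(
    record: SampleRecord | str | Path,
    resolution: int,
    image_root: str | Path = ".",
) -> np.ndarray:
    """Load one record's image and resize it to resolution x resolution x 3."""
    if isinstance(record, SampleRecord):
        path = Path(image_root) / record.image_path
    else:
        path = Path(record)
    arr = load_image_raw(path)
    return resize_bilinear(arr, resolution, resolution)
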