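"""Image/mask pair loading, dataset manifests, split protocols, and the
flip + translate training-set augmentation.

Augmentation is always applied *after* splitting and only to training
images; every augmented record carries the ``root_id`` of the original it
descends from so leakage can be audited.

The published augmentation profiles (applied to the training partition):

==========  ======  ===========  ================
dataset     images  split        augmented target
==========  ======  ===========  ================
DRIVE           40  20 / 20                 3,000
CHASE-DB1       28  20 / 8                  1,500
STARE           20  leave-1-out             1,300
==========  ======  ===========  ================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import ConfigurationError


class ValidationError(ValueError):
    """Image/mask pair or manifest fails a structural check."""


@dataclass
class SampleRecord:
    """One image+mask pair with provenance.

    ``provenance`` is one of original / vflip / hflip / translated;
    ``offset`` is the (dx, dy) translation in pixels, (0, 0) otherwise.
    ``root_id`` names the original ancestor (lineage id for leakage checks).
    """

    id: str
    image_path: str = ""
    mask_path: str = ""
    split: str = "train"
    provenance: str = "original"
    offset: tuple[int, int] = (0, 0)
    root_id: str = ""
    image: Optional[np.ndarray] = field(default=None, repr=False)  # (H,W,3) float in [0,1]
    mask: Optional[np.ndarray] = field(default=None, repr=False)   # (H,W) uint8 {0,1}

    def __post_init__(self):
        if not self.root_id:
            self.root_id = self.id


@dataclass
class SplitProtocol:
    """Either a single fixed split or leave-one-out cross-validation."""

    name: str  # "fixed_split" | "leave_one_out"
    n_train: int = 0
    n_test: int = 0
    n_folds: int = 0


DATASET_PROFILES = {
    "drive": {"n_images": 40,
              "protocol": SplitProtocol("fixed_split", n_train=20, n_test=20),
              "augment_target": 3000},
    "chase-db1": {"n_images": 28,
                  "protocol": SplitProtocol("fixed_split", n_train=20, n_test=8),
                  "augment_target": 1500},
    "stare": {"n_images": 20,
              "protocol": SplitProtocol("leave_one_out", n_folds=20),
              "augment_target": 1300},
}


def load_pair(image_path: str | Path, mask_path: str | Path,
              binarize_threshold: int = 0) -> SampleRecord:
    """Load an RGB image and its expert mask; scale the image to [0, 1] and
    binarize the mask (``value > threshold`` -> vessel)."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        img = iio.imread(image_path)
    except OSError as e:
        raise IOError(f"cannot read image {image_path}: {e}") from e
    try:
        msk = iio.imread(mask_path)
    except OSError as e:
        raise IOError(f"cannot read mask {mask_path}: {e}") from e
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    img = img[..., :3]
    if msk.ndim == 3:
        msk = msk[..., 0]
    if img.shape[:2] != msk.shape[:2]:
        raise ValidationError(
            f"image {img.shape[:2]} and mask {msk.shape[:2]} sizes differ "
            f"({image_path.name} / {mask_path.name})")
    image = img.astype(np.float32) / 255.0
    mask = (msk > binarize_threshold).astype(np.uint8)
    return SampleRecord(id=image_path.stem, image_path=str(image_path),
                        mask_path=str(mask_path), image=image, mask=mask)


def _flip(rec: SampleRecord, axis: int, tag: str) -> SampleRecord:
    return replace(rec, id=f"{rec.id}_{tag}", provenance=tag,
                   image=np.flip(rec.image, axis=axis).copy(),
                   mask=np.flip(rec.mask, axis=axis).copy(),
                   root_id=rec.root_id)


def flip_augment(records: list[SampleRecord]) -> list[SampleRecord]:
    """Originals plus vertical and horizontal flips: n records -> 3n.

    The same flip is applied to image and mask (20 originals -> 60 images,
    as in the published recipe).
    """
    out = list(records)
    out += [_flip(r, axis=0, tag="vflip") for r in records]
    out += [_flip(r, axis=1, tag="hflip") for r in records]
    return out


def _translate(arr: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift by (dx right, dy down), zero-filling vacated pixels."""
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys_src = slice(max(0, -dy), min(h, h - dy))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[ys_dst, xs_dst] = arr[ys_src, xs_src]
    return out


def translate_augment(records: list[SampleRecord], target_count: int,
                      max_offset: int = 50, seed: int = 0) -> list[SampleRecord]:
    """Grow a record list to exactly ``target_count`` by cycling through it
    with random integer translations (uniform on [-max_offset, max_offset]^2,
    zero fill) and a random inherited flip in {none, vflip, hflip}.

    Fully reproducible from ``seed``; the output begins with the input
    records unchanged.
    """
    if target_count < len(records):
        raise ValidationError(
            f"target_count {target_count} < {len(records)} input records")
    h, w = records[0].image.shape[:2]
    if max_offset >= min(h, w):
        raise ConfigurationError(
            f"max_offset {max_offset} >= smallest image dimension {min(h, w)}")
    rng = np.random.default_rng(seed)
    out = list(records)
    i = 0
    k = 0
    while len(out) < target_count:
        src = records[i % len(records)]
        dx, dy = (int(v) for v in rng.integers(-max_offset, max_offset + 1, 2))
        img = _translate(src.image, dx, dy)
        msk = _translate(src.mask, dx, dy)
        flip_choice = rng.integers(0, 3)
        if flip_choice == 1:
            img, msk = np.flip(img, 0).copy(), np.flip(msk, 0).copy()
        elif flip_choice == 2:
            img, msk = np.flip(img, 1).copy(), np.flip(msk, 1).copy()
        out.append(replace(src, id=f"{src.id}_t{k}", provenance="translated",
                           offset=(dx, dy), image=img, mask=msk,
                           root_id=src.root_id))
        i += 1
        k += 1
    return out


def make_splits(records: list[SampleRecord], protocol: SplitProtocol,
                seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Fold assignments as (train ids, test ids) lists.

    ``fixed_split``: one fold, the first ``n_train`` ids in sorted order
    train (the canonical deterministic assignment).  ``leave_one_out``: one
    fold per image, each testing exactly one image.
    """
    ids = sorted(r.id for r in records)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ids in manifest")
    if protocol.name == "fixed_split":
        if protocol.n_train + protocol.n_test != len(ids):
            raise ValidationError(
                f"fixed_split {protocol.n_train}+{protocol.n_test} != "
                f"manifest size {len(ids)}")
        return [(ids[:protocol.n_train], ids[protocol.n_train:])]
    if protocol.name == "leave_one_out":
        if protocol.n_folds and protocol.n_folds != len(ids):
            raise ValidationError(
                f"leave_one_out n_folds {protocol.n_folds} != "
                f"manifest size {len(ids)}")
        return [([i for i in ids if i != test], [test]) for test in ids]
    raise ValidationError(f"unknown protocol {protocol.name!r}")


# ------------------------------------------------------------------ manifests

MANIFEST_COLUMNS = ["id", "image_path", "mask_path", "split", "provenance",
                    "dx", "dy", "root_id"]


def save_manifest(records: list[SampleRecord], path: str | Path) -> None:
    rows = [{"id": r.id, "image_path": r.image_path, "mask_path": r.mask_path,
             "split": r.split, "provenance": r.provenance,
             "dx": r.offset[0], "dy": r.offset[1], "root_id": r.root_id}
            for r in records]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def load_manifest(path: str | Path, load_arrays: bool = True) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype={"id": str, "root_id": str})
    records = []
    for row in df.itertuples(index=False):
        if load_arrays:
            rec = load_pair(row.image_path, row.mask_path)
        else:
            rec = SampleRecord(id=str(row.id), image_path=row.image_path,
                               mask_path=row.mask_path)
        rec.id = str(row.id)
        rec.split = row.split
        rec.provenance = row.provenance
        rec.offset = (int(row.dx), int(row.dy))
        rec.root_id = str(row.root_id)
        records.append(rec)
    return records


def write_pair(rec: SampleRecord, out_dir: str | Path) -> SampleRecord:
    """Write a record's arrays as 8-bit PNGs (image RGB, mask {0, 255})."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_path = out_dir / f"{rec.id}.png"
    mask_path = out_dir / f"{rec.id}_mask.png"
    iio.imwrite(image_path, (np.clip(rec.image, 0, 1) * 255).astype(np.uint8))
    iio.imwrite(mask_path, (rec.mask * 255).astype(np.uint8))
    rec.image_path = str(image_path)
    rec.mask_path = str(mask_path)
    return rec
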