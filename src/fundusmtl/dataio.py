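"""On-disk dataset layout: images/, masks/, fovea.csv, labels.csv.

The layout mirrors how REFUGE-style data is usually arranged, and the
synthetic generator writes exactly the same structure, so synthetic and
real datasets are interchangeable.  Masks are single-channel 8-bit PNGs
with the tri-level convention: dark pixels are cup (hence also disc),
mid-gray pixels disc only, light pixels background.  Decoding uses
tolerant thresholds (<=64 cup, <=192 disc) so that resampled or
re-encoded masks still decode; a strict mode insists on exact levels.

Coordinates everywhere are 0-based with x = column and y = row,
fractional values allowed.  Loading resizes images bilinearly and masks
with nearest-neighbor to the model's input size and rescales the fovea
coordinates by the same factors.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import FundusDataset

TRI_LEVELS = {"oc": 0, "od": 128, "background": 255}


@dataclass(frozen=True)
class MaskEncoding:
    """Gray-value semantics of tri-level mask PNGs."""

    oc_max: int = 64     # gray <= oc_max  -> inside cup (and disc)
    od_max: int = 192    # gray <= od_max  -> inside disc
    strict: bool = False  # require exactly the canonical {0, 128, 255} levels

    def decode(self, gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gray image -> (od_mask, oc_mask); OC implies OD."""
        gray = np.asarray(gray)
        if self.strict:
            bad = set(np.unique(gray)) - set(TRI_LEVELS.values())
            if bad:
                raise ValueError(f"unexpected gray values under strict encoding: {sorted(bad)}")
        oc = gray <= self.oc_max
        od = gray <= self.od_max
        return od.astype(np.uint8), oc.astype(np.uint8)

    @staticmethod
    def encode(od_mask: np.ndarray, oc_mask: np.ndarray) -> np.ndarray:
        gray = np.full(od_mask.shape, TRI_LEVELS["background"], dtype=np.uint8)
        gray[od_mask.astype(bool)] = TRI_LEVELS["od"]
        gray[oc_mask.astype(bool)] = TRI_LEVELS["oc"]
        return gray


@dataclass
class IndexItem:
    id: str
    image_path: Path
    mask_path: Path | None = None
    fovea: tuple | None = None      # (x, y) in ORIGINAL pixel coordinates
    label: int | None = None
    split: str = "train"


@dataclass
class DatasetIndex:
    items: list = field(default_factory=list)

    def __post_init__(self):
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image ids in dataset index")


def _read_csv_map(path: Path, value_cols) -> dict:
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["image_id"]] = tuple(float(row[c]) for c in value_cols)
    return out


def build_index(root) -> DatasetIndex:
    """Scan a dataset directory into an index, validating references."""
    root = Path(root)
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    fovea = _read_csv_map(root / "fovea.csv", ("fovea_x", "fovea_y")) if (root / "fovea.csv").exists() else {}
    labels = _read_csv_map(root / "labels.csv", ("glaucoma",)) if (root / "labels.csv").exists() else {}
    items = []
    for p in sorted(img_dir.iterdir()):
        if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        iid = p.stem
        mask = root / "masks" / f"{iid}.png"
        items.append(IndexItem(
            id=iid,
            image_path=p,
            mask_path=mask if mask.exists() else None,
            fovea=fovea.get(iid),
            label=None if iid not in labels else int(labels[iid][0]),
        ))
    return DatasetIndex(items=items)


def load_dataset(root, input_size: int, mask_encoding: MaskEncoding = MaskEncoding()) -> tuple[DatasetIndex, FundusDataset]:
    """Load and resize a dataset directory to ``input_size``.

    Images are decoded to RGB in [0, 1] and resized bilinearly; masks
    with nearest-neighbor; fovea coordinates are rescaled by the same
    factors.  Items missing a target carry NaN fovea rows / -1 labels /
    zero masks (callers check the per-item flags on the index).
    """
    index = build_index(root)
    n = len(index.items)
    if n == 0:
        raise FileNotFoundError(f"no images found under {root}")
    images = np.empty((n, 3, input_size, input_size), dtype=np.float32)
    any_mask = any(it.mask_path for it in index.items)
    od = np.zeros((n, input_size, input_size), dtype=np.uint8) if any_mask else None
    oc = np.zeros_like(od) if any_mask else None
    fovea = np.full((n, 2), np.nan)
    labels = np.full(n, -1, dtype=np.int8)
    errors = []
    for i, it in enumerate(index.items):
        with Image.open(it.image_path) as im:
            im = im.convert("RGB")
            w0, h0 = im.size
            arr = np.asarray(im.resize((input_size, input_size), Image.BILINEAR), dtype=np.float32)
        images[i] = (arr / 255.0).transpose(2, 0, 1)
        if it.mask_path is not None:
            with Image.open(it.mask_path) as mm:
                mm = mm.convert("L").resize((input_size, input_size), Image.NEAREST)
                try:
                    od[i], oc[i] = mask_encoding.decode(np.asarray(mm))
                except ValueError as e:
                    errors.append(f"{it.id}: {e}")
        if it.fovea is not None:
            x, y = it.fovea
            if not (0 <= x < w0 and 0 <= y < h0):
                errors.append(f"{it.id}: fovea ({x}, {y}) outside {w0}x{h0} image")
            fovea[i] = (x * input_size / w0, y * input_size / h0)
        if it.label is not None:
            labels[i] = it.label
    if errors:
        raise ValueError("dataset errors:\n" + "\n".join(errors))
    return index, FundusDataset(
        images=images, od_masks=od, oc_masks=oc,
        fovea=fovea if np.isfinite(fovea).any() else None,
        labels=labels if (labels >= 0).any() else None,
        ids=[it.id for it in index.items],
    )


def write_dataset(dataset: FundusDataset, root):
    """Write a dataset in the standard directory layout."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    if dataset.od_masks is not None:
        (root / "masks").mkdir(exist_ok=True)
    for i, iid in enumerate(dataset.ids):
        rgb = (np.clip(dataset.images[i], 0, 1) * 255).round().astype(np.uint8).transpose(1, 2, 0)
        Image.fromarray(rgb).save(root / "images" / f"{iid}.png")
        if dataset.od_masks is not None:
            gray = MaskEncoding.encode(dataset.od_masks[i], dataset.oc_masks[i])
            Image.fromarray(gray, mode="L").save(root / "masks" / f"{iid}.png")
    if dataset.fovea is not None:
        with open(root / "fovea.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image_id", "fovea_x", "fovea_y"])
            for iid, (x, y) in zip(dataset.ids, dataset.fovea):
                w.writerow([iid, repr(float(x)), repr(float(y))])
    if dataset.labels is not None:
        with open(root / "labels.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image_id", "glaucoma"])
            for iid, lab in zip(dataset.ids, dataset.labels):
                w.writerow([iid, int(lab)])
    if dataset.vcdr_true is not None:
        with open(root / "vcdr.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image_id", "vcdr"])
            for iid, v in zip(dataset.ids, dataset.vcdr_true):
                w.writerow([iid, repr(float(v))])


def write_predictions_csv(report, path):
    """Per-image predictions CSV from a MetricsReport."""
    cols = ["image_id", "prob_fc", "prob_lin", "prob_avg", "label_pred", "vcdr", "fovea_x", "fovea_y"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for rec in report.per_image:
            w.writerow([rec.get(c, "") if rec.get(c) is not None else "" for c in cols])


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
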