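"""DICOM-to-dataset preprocessing: convert, filter, strip, resize, split.

The pipeline mirrors the preparation used for PD-vs-HC slice
classification: read each DICOM slice, window it to 8 bits, drop near-blank
("empty") slices whose mean intensity falls below a threshold (default 30),
mask out non-brain pixels (Otsu threshold, largest connected component,
morphological closing), crop to the head bounding box, resample to
224x224 with the grey channel replicated to 3, and carve train/validation/
test partitions with the floor convention: test = floor(0.2*n) then
validation = floor(0.2*(n - test)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk
from skimage.transform import resize

__all__ = [
    "ImageRecord",
    "DatasetManifest",
    "PipelineConfig",
    "StrippingError",
    "convert_dicom",
    "is_empty",
    "skull_strip",
    "crop_and_resize",
    "split_dataset",
    "run_pipeline",
]

LABELS = ("PD", "HC")


class FormatError(ValueError):
    """Unreadable image file or missing pixel data."""


class StrippingError(ValueError):
    """Skull stripping produced an empty foreground mask."""


@dataclass
class ImageRecord:
    subject_id: str
    label: str
    pixels: np.ndarray  # uint8, (H, W) or (H, W, 3)
    path: str = ""
    modality: str = "t1t2"
    mask: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class DatasetManifest:
    records: list[ImageRecord]
    splits: dict[str, str]  # record path -> train | validation | test
    seed: int
    filtered: list[str] = field(default_factory=list)  # paths removed as empty
    errors: list[str] = field(default_factory=list)

    def counts(self) -> pd.DataFrame:
        rows = [
            {"path": r.path, "label": r.label, "split": self.splits[r.path]}
            for r in self.records
        ]
        df = pd.DataFrame(rows)
        return df.groupby(["split", "label"]).size().unstack(fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "path": r.path,
                    "subject_id": r.subject_id,
                    "label": r.label,
                    "split": self.splits[r.path],
                    "empty": bool(r.flags.get("empty", False)),
                    "stripped": bool(r.flags.get("stripped", False)),
                }
                for r in self.records
            ]
        )

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / "manifest.csv", index=False)
        per_split = {
            s: int(sum(1 for p in self.splits.values() if p == s))
            for s in ("train", "validation", "test")
        }
        summary = {
            "seed": self.seed,
            "n_retained": len(self.records),
            "n_filtered": len(self.filtered),
            "filtered": sorted(self.filtered),
            "errors": sorted(self.errors),
            "splits": per_split,
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


@dataclass(frozen=True)
class PipelineConfig:
    input_dir: str
    output_dir: str
    empty_threshold: float = 30.0
    target_size: tuple[int, int, int] = (224, 224, 3)
    test_fraction: float = 0.2
    validation_fraction: float = 0.2
    seed: int = 0
    image_format: str = "png"  # "png" (lossless) or "jpeg" (quality 95)
    by_subject: bool = False

    def __post_init__(self):
        if not (0 < self.test_fraction < 1 and 0 < self.validation_fraction < 1):
            raise ValueError("split fractions must lie in (0, 1)")
        if self.empty_threshold < 0:
            raise ValueError("empty_threshold must be >= 0")


def _window_to_uint8(arr: np.ndarray, ds: pydicom.Dataset) -> np.ndarray:
    """Linear window of stored values into [0, 255]."""
    arr = arr.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1) or 1)
    intercept = float(getattr(ds, "RescaleIntercept", 0) or 0)
    arr = arr * slope + intercept
    center = getattr(ds, "WindowCenter", None)
    width = getattr(ds, "WindowWidth", None)
    if center is not None and width is not None:
        center = float(center[0] if isinstance(center, pydicom.multival.MultiValue) else center)
        width = float(width[0] if isinstance(width, pydicom.multival.MultiValue) else width)
        lo = center - width / 2.0
        hi = center + width / 2.0
    else:
        lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    out = (arr - lo) / (hi - lo)
    return np.round(np.clip(out, 0.0, 1.0) * 255.0).astype(np.uint8)


def convert_dicom(path: str | Path) -> ImageRecord:
    """Read one DICOM slice and window its pixel data to an 8-bit image.

    The class label is taken from the parent directory name when it is
    "PD" or "HC", otherwise left as "HC" for the caller to overwrite.
    Geometry is preserved; resizing happens later in the pipeline.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"cannot read DICOM pixel data from {path}: {exc}") from exc
    label = path.parent.name if path.parent.name in LABELS else "HC"
    modality = "datscan" if getattr(ds, "Modality", "") == "NM" else "t1t2"
    return ImageRecord(
        subject_id=str(getattr(ds, "PatientID", path.stem)),
        label=label,
        pixels=_window_to_uint8(arr, ds),
        path=str(path),
        modality=modality,
    )


def is_empty(record: ImageRecord, threshold: float = 30.0) -> bool:
    """Empty-slice criterion: mean 8-bit intensity below ``threshold``."""
    return bool(float(record.pixels.mean()) < threshold)


def skull_strip(record: ImageRecord) -> ImageRecord:
    """Zero out non-head pixels.

    Head mask = Otsu global threshold, largest connected component,
    morphological closing and hole filling.  Raises `StrippingError` when no
    foreground survives (e.g. a blank slice).
    """
    gray = record.pixels if record.pixels.ndim == 2 else record.pixels[..., 0]
    if gray.max() == gray.min():
        raise StrippingError(f"no foreground in {record.path or '<in-memory>'}")
    thr = threshold_otsu(gray)
    fg = gray > thr
    if not fg.any():
        raise StrippingError(f"empty mask after Otsu in {record.path or '<in-memory>'}")
    labels = cc_label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    pad = 6  # margin so closing cannot erode the image border
    padded = np.pad(mask, pad)
    padded = ndimage.binary_closing(padded, structure=disk(5))
    mask = padded[pad:-pad, pad:-pad]
    mask = ndimage.binary_fill_holes(mask)
    stripped = gray.copy()
    stripped[~mask] = 0
    return replace(
        record,
        pixels=stripped,
        mask=mask,
        flags={**record.flags, "stripped": True, "mask_area": int(mask.sum())},
    )


def crop_and_resize(
    record: ImageRecord, target: tuple[int, int, int] = (224, 224, 3)
) -> ImageRecord:
    """Crop to the mask (or nonzero) bounding box, square-pad, resample.

    Output is uint8 ``target`` shaped, grayscale replicated across channels.
    """
    gray = record.pixels if record.pixels.ndim == 2 else record.pixels[..., 0]
    source = record.mask if record.mask is not None else gray > 0
    ys, xs = np.nonzero(source)
    if ys.size == 0:
        raise ValueError(f"degenerate bounding box in {record.path or '<in-memory>'}")
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    crop = gray[y0:y1, x0:x1]
    h, w = crop.shape
    side = max(h, w)
    pad_y, pad_x = side - h, side - w
    crop = np.pad(
        crop,
        ((pad_y // 2, pad_y - pad_y // 2), (pad_x // 2, pad_x - pad_x // 2)),
    )
    out = resize(crop.astype(float), target[:2], order=1, anti_aliasing=True, preserve_range=True)
    out = np.round(np.clip(out, 0, 255)).astype(np.uint8)
    out3 = np.repeat(out[:, :, None], target[2], axis=2)
    return replace(record, pixels=out3, flags={**record.flags, "resized": True})


def _largest_remainder(counts: dict[str, int], k_total: int) -> dict[str, int]:
    """Split k_total across classes proportionally to counts (floor totals fixed)."""
    n = sum(counts.values())
    quotas = {c: k_total * counts[c] / n for c in counts}
    base = {c: int(np.floor(quotas[c])) for c in counts}
    short = k_total - sum(base.values())
    order = sorted(counts, key=lambda c: (-(quotas[c] - base[c]), -counts[c], c))
    for c in order[:short]:
        base[c] += 1
    # never take more than a class has
    for c in counts:
        base[c] = min(base[c], counts[c])
    return base


def split_dataset(
    records: list[ImageRecord],
    seed: int = 0,
    test_fraction: float = 0.2,
    validation_fraction: float = 0.2,
    by_subject: bool = False,
) -> DatasetManifest:
    """Assign train/validation/test with the floor convention.

    test = floor(test_fraction * n); validation = floor(validation_fraction
    * (n - test)); stratification by class is best-effort via largest
    remainder so the totals are fixed.  ``by_subject`` keeps all slices of
    one subject in the same split (leakage-safe mode; split sizes then only
    approximate the floor rule).
    """
    labels_present = {r.label for r in records}
    for lab in LABELS:
        if lab not in labels_present:
            raise ValueError(f"class {lab} absent from records")
    rng = np.random.default_rng(seed)
    n = len(records)
    n_test = int(np.floor(test_fraction * n))
    n_val = int(np.floor(validation_fraction * (n - n_test)))

    if by_subject:
        return _split_by_subject(records, rng, n_test, n_val, seed)

    by_class: dict[str, list[int]] = {lab: [] for lab in LABELS}
    for i, r in enumerate(records):
        by_class[r.label].append(i)
    for lab in LABELS:
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        by_class[lab] = idx.tolist()

    class_counts = {lab: len(by_class[lab]) for lab in LABELS}
    test_per_class = _largest_remainder(class_counts, n_test)
    remaining = {lab: class_counts[lab] - test_per_class[lab] for lab in LABELS}
    val_per_class = _largest_remainder(remaining, n_val)

    splits: dict[str, str] = {}
    for lab in LABELS:
        idx = by_class[lab]
        k_test, k_val = test_per_class[lab], val_per_class[lab]
        for i in idx[:k_test]:
            splits[records[i].path] = "test"
        for i in idx[k_test : k_test + k_val]:
            splits[records[i].path] = "validation"
        for i in idx[k_test + k_val :]:
            splits[records[i].path] = "train"
    return DatasetManifest(records=records, splits=splits, seed=seed)


def _split_by_subject(records, rng, n_test, n_val, seed) -> DatasetManifest:
    subjects: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        subjects.setdefault(r.subject_id, []).append(i)
    names = sorted(subjects)
    order = np.array(names, dtype=object)
    rng.shuffle(order)
    splits: dict[str, str] = {}
    taken_test = taken_val = 0
    for s in order:
        size = len(subjects[s])
        if taken_test < n_test:
            dest = "test"
            taken_test += size
        elif taken_val < n_val:
            dest = "validation"
            taken_val += size
        else:
            dest = "train"
        for i in subjects[s]:
            splits[records[i].path] = dest
    return DatasetManifest(records=records, splits=splits, seed=seed)


def run_pipeline(config: PipelineConfig) -> DatasetManifest:
    """Full pipeline: convert, filter empties, strip, resize, split, save.

    Single-file failures are logged and skipped; the manifest, per-image
    outputs (PNG by default) and a JSON summary are written to
    ``config.output_dir``.  Same inputs and seed give identical outputs.
    """
    in_dir = Path(config.input_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"input directory {in_dir} does not exist")
    paths = sorted(p for p in in_dir.rglob("*") if p.suffix.lower() in (".dcm", ".dic"))
    if not paths:
        raise FileNotFoundError(f"no DICOM files under {in_dir}")
    out_dir = Path(config.output_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    retained: list[ImageRecord] = []
    filtered: list[str] = []
    errors: list[str] = []
    for path in paths:
        try:
            rec = convert_dicom(path)
            if is_empty(rec, config.empty_threshold):
                filtered.append(str(path))
                continue
            rec = skull_strip(rec)
            rec = crop_and_resize(rec, config.target_size)
        except (FormatError, StrippingError, ValueError) as exc:
            errors.append(f"{path}: {exc}")
            continue
        ext = "png" if config.image_format == "png" else "jpg"
        out_name = f"{rec.label.lower()}_{path.stem}.{ext}"
        out_path = img_dir / out_name
        img = Image.fromarray(rec.pixels)
        if ext == "jpg":
            img.save(out_path, quality=95)
        else:
            img.save(out_path)
        rec = replace(rec, path=str(out_path))
        retained.append(rec)

    manifest = split_dataset(
        retained,
        seed=config.seed,
        test_fraction=config.test_fraction,
        validation_fraction=config.validation_fraction,
        by_subject=config.by_subject,
    )
    manifest.filtered = filtered
    manifest.errors = errors
    manifest.save(out_dir)
    return manifest
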