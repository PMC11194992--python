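"""Deterministic two-class brain-phantom generator.

Every other part of the toolkit is testable against this module: it emits
axial head phantoms — an elliptical skull ring, textured interior tissue,
and two small striatal foci whose brightness and shape differ by class —
written as 16-bit single-frame DICOM files with a CSV truth manifest and
per-image head masks.  In the DaTscan idiom, healthy-control foci are
bright and elongated (the "comma") while PD foci are dimmer and rounder
(the "dot"); the ``focus_separation`` parameter is the mean intensity gap
between the classes and can be set to 0 for a null effect.

The emulation targets image *structure* the pipeline needs (blank slices,
a strippable skull, a learnable class signal), not MRI or SPECT physics.
A controllable fraction of slices is blank to exercise the empty-image
filter.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from PIL import Image
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = ["PhantomSpec", "generate_image", "generate_dataset"]

_UID_ROOT = "1.2.826.0.1.3680043.10.1405."


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal parameters of the phantom population.

    Intensities are in the 12-bit stored-pixel scale (0..4095).
    """

    size: tuple[int, int] = (256, 256)
    skull_radius: tuple[float, float] = (100.0, 85.0)  # outer semi-axes (y, x)
    skull_thickness: float = 12.0
    skull_intensity: float = 3000.0
    tissue_intensity: float = 1200.0
    texture_noise: float = 120.0  # s.d. of the smoothed tissue texture
    focus_base_intensity: float = 1600.0  # HC focus amplitude above tissue
    focus_separation: float = 600.0  # mean HC-PD focus amplitude gap
    focus_jitter: float = 80.0  # s.d. of per-image focus amplitude
    blank_fraction: float = 0.1
    modality: str = "datscan"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.blank_fraction < 1:
            raise ValueError("blank_fraction must be in [0, 1)")
        if self.modality not in ("t1t2", "datscan"):
            raise ValueError("modality must be 't1t2' or 'datscan'")


def _ellipse_mask(shape, center, semi_axes, angle=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    y = yy - center[0]
    x = xx - center[1]
    if angle:
        ca, sa = np.cos(angle), np.sin(angle)
        y, x = ca * y - sa * x, sa * y + ca * x
    return (y / semi_axes[0]) ** 2 + (x / semi_axes[1]) ** 2 <= 1.0


def _smooth(noise: np.ndarray, passes: int = 2) -> np.ndarray:
    # cheap separable box smoothing; keeps the generator dependency-light
    for _ in range(passes):
        noise = (
            noise
            + np.roll(noise, 1, 0) + np.roll(noise, -1, 0)
            + np.roll(noise, 1, 1) + np.roll(noise, -1, 1)
        ) / 5.0
    return noise


def generate_image(
    spec: PhantomSpec, label: str, rng: np.random.Generator, blank: bool = False
) -> tuple[np.ndarray, np.ndarray, dict]:
    """One phantom: (16-bit pixel matrix, boolean head mask, focus params).

    ``label`` is "PD" or "HC".  A blank draw returns an all-zero image with
    an empty mask.  The class signal: both striatal foci share a mean
    amplitude of ``focus_base_intensity`` for HC and
    ``focus_base_intensity - focus_separation`` for PD, and HC foci are
    elongated (comma-like) while PD foci are round (dot-like).
    """
    if label not in ("PD", "HC"):
        raise ValueError("label must be 'PD' or 'HC'")
    h, w = spec.size
    if blank:
        return (
            np.zeros(spec.size, dtype=np.uint16),
            np.zeros(spec.size, dtype=bool),
            {"is_blank": True, "focus_amplitude": 0.0},
        )
    center = (h / 2.0, w / 2.0)
    outer = _ellipse_mask(spec.size, center, spec.skull_radius)
    inner = _ellipse_mask(
        spec.size,
        center,
        (spec.skull_radius[0] - spec.skull_thickness, spec.skull_radius[1] - spec.skull_thickness),
    )
    img = np.zeros(spec.size, dtype=float)
    img[outer & ~inner] = spec.skull_intensity
    texture = _smooth(rng.standard_normal(spec.size)) * spec.texture_noise * 3.0
    img[inner] = spec.tissue_intensity + texture[inner]

    amp_mean = spec.focus_base_intensity - (spec.focus_separation if label == "PD" else 0.0)
    amplitude = amp_mean + rng.normal(0.0, spec.focus_jitter)
    # PD: round "dot" foci; HC: elongated "comma" foci
    sigmas = (5.0, 5.0) if label == "PD" else (4.0, 10.0)
    yy, xx = np.mgrid[:h, :w].astype(float)
    offsets = ((-10.0, -26.0), (-10.0, 26.0))
    for i, (dy, dx) in enumerate(offsets):
        cy, cx = center[0] + dy, center[1] + dx
        angle = (0.6 if i == 0 else -0.6) if label == "HC" else 0.0
        y = yy - cy
        x = xx - cx
        if angle:
            ca, sa = np.cos(angle), np.sin(angle)
            y, x = ca * y - sa * x, sa * y + ca * x
        blob = np.exp(-0.5 * ((y / sigmas[0]) ** 2 + (x / sigmas[1]) ** 2))
        img += amplitude * blob * inner
    img = np.clip(img, 0, 4095)
    return img.astype(np.uint16), outer, {"is_blank": False, "focus_amplitude": float(amplitude)}


def _write_dicom(path: Path, pixels: np.ndarray, subject_id: str, modality: str, uid_tag: str):
    """Minimal deterministic single-frame secondary-capture DICOM."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(
        prefix=_UID_ROOT, entropy_srcs=[uid_tag]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM" if modality == "datscan" else "MR"
    ds.PatientID = subject_id
    ds.PatientName = subject_id
    ds.StudyDate = "20240101"  # fixed so output is byte-stable across runs
    ds.ContentDate = "20240101"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 12
    ds.HighBit = 11
    ds.PixelRepresentation = 0
    ds.RescaleIntercept = 0
    ds.RescaleSlope = 1
    ds.WindowCenter = 2048
    ds.WindowWidth = 4096
    ds.PixelData = pixels.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)


def generate_dataset(
    spec: PhantomSpec,
    n_pd: int,
    n_hc: int,
    out_dir: str | Path,
    write_masks: bool = True,
) -> pd.DataFrame:
    """Write a labelled phantom dataset and return its truth manifest.

    Files land in ``out_dir/PD`` and ``out_dir/HC``; head masks (PNG) go to
    ``out_dir/masks``.  Exactly ``round(blank_fraction * n)`` images are
    blank, spread deterministically across the set.  Fixed seed gives
    byte-identical pixel data and manifest.
    """
    if n_pd < 1 or n_hc < 1:
        raise ValueError("need at least one image per class")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    n = n_pd + n_hc
    n_blank = round(spec.blank_fraction * n)
    blank_idx = set(rng.choice(n, size=n_blank, replace=False).tolist())

    labels = ["PD"] * n_pd + ["HC"] * n_hc
    rows = []
    for i, label in enumerate(labels):
        subject = f"{label}{i % max(1, (n_pd if label == 'PD' else n_hc) // 5):03d}"
        pixels, mask, info = generate_image(spec, label, rng, blank=i in blank_idx)
        cls_dir = out_dir / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        fname = f"{label.lower()}_{i:04d}.dcm"
        path = cls_dir / fname
        _write_dicom(path, pixels, subject, spec.modality, uid_tag=f"{spec.seed}:{i}")
        mask_path = ""
        if write_masks:
            (out_dir / "masks").mkdir(parents=True, exist_ok=True)
            mask_path = str(Path("masks") / f"{label.lower()}_{i:04d}_mask.png")
            Image.fromarray((mask * 255).astype(np.uint8)).save(out_dir / mask_path)
        rows.append(
            {
                "path": str(Path(label) / fname),
                "subject_id": subject,
                "label": label,
                "is_blank": info["is_blank"],
                "focus_amplitude": info["focus_amplitude"],
                "mask_path": mask_path,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "truth_manifest.csv", index=False)
    return manifest
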