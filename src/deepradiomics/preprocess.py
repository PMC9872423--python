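"""Image scaling, noise corruption and train/test partitioning.

Pixel values are min–max scaled to [0, 1] per image before any modelling.
Denoising-autoencoder training corrupts the scaled images with additive
Gaussian noise, ``noisy = raw + noise_level * N(0, 1)`` elementwise, with no
clipping — the reconstruction loss is always computed against the clean
image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImageRecord",
    "NoiseConfig",
    "minmax_scale",
    "add_noise",
    "split_train_test",
    "load_png_dir",
    "load_dicom_dir",
    "scale_images",
]


@dataclass
class ImageRecord:
    """One 2-D grayscale slice tagged with its patient of origin."""

    patient_id: str
    image_id: str
    pixels: np.ndarray


@dataclass
class NoiseConfig:
    noise_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.noise_level) or self.noise_level < 0:
            raise ValueError("NoiseConfig.noise_level must be a finite real >= 0")


def minmax_scale(pixels: np.ndarray) -> np.ndarray:
    """Scale a pixel matrix to [0, 1] as (x - min) / (max - min).

    A constant matrix carries no signal and maps to all zeros.
    """
    pixels = np.asarray(pixels, dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("pixel matrix contains non-finite values")
    lo = pixels.min()
    span = pixels.max() - lo
    if span == 0:
        return np.zeros_like(pixels)
    return (pixels - lo) / span


def scale_images(images: Iterable[ImageRecord]) -> list[ImageRecord]:
    """Min–max scale every image, preserving ids."""
    return [ImageRecord(r.patient_id, r.image_id, minmax_scale(r.pixels))
            for r in images]


def add_noise(images: np.ndarray | Sequence[np.ndarray],
              cfg: NoiseConfig) -> np.ndarray:
    """Corrupt scaled images with additive Gaussian noise of sd ``noise_level``.

    Values are not clipped back into [0, 1]; the loss downstream compares
    reconstructions to the clean input. Deterministic given ``cfg.seed``.
    """
    arr = np.asarray(images, dtype=float)
    if cfg.noise_level == 0:
        return arr.copy()
    rng = np.random.default_rng(cfg.seed)
    return arr + cfg.noise_level * rng.standard_normal(arr.shape)


def split_train_test(images: Sequence[ImageRecord], ratio: float, seed: int = 0,
                     group_by_patient: bool = False,
                     ) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Random disjoint, exhaustive train/test split of the image list.

    ``ratio`` is the train fraction. By default units are images; with
    ``group_by_patient`` units are patients, so no patient appears in both
    sets.  Deterministic given ``seed``.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie strictly between 0 and 1")
    if len(images) < 2:
        raise ValueError("need at least 2 images to split")
    rng = np.random.default_rng(seed)
    if group_by_patient:
        patients = sorted({r.patient_id for r in images})
        order = rng.permutation(len(patients))
        n_train = int(round(ratio * len(patients)))
        n_train = min(max(n_train, 1), len(patients) - 1)
        train_p = {patients[i] for i in order[:n_train]}
        train = [r for r in images if r.patient_id in train_p]
        test = [r for r in images if r.patient_id not in train_p]
    else:
        order = rng.permutation(len(images))
        n_train = int(round(ratio * len(images)))
        n_train = min(max(n_train, 1), len(images) - 1)
        train = [images[i] for i in order[:n_train]]
        test = [images[i] for i in order[n_train:]]
    return train, test


def load_png_dir(path: str | Path, image_size: int | None = None,
                 ) -> list[ImageRecord]:
    """Read a directory of ``<patient>_<image>.png`` grayscale slices.

    Handles 8- and 16-bit PNG; pixel values are returned unscaled (floats).
    """
    import imageio.v3 as iio

    path = Path(path)
    records = []
    for f in sorted(path.glob("*.png")):
        pix = np.asarray(iio.imread(f), dtype=float)
        if pix.ndim == 3:  # collapse any accidental channel axis
            pix = pix.mean(axis=2)
        if image_size is not None and pix.shape != (image_size, image_size):
            raise ValueError(f"{f.name}: expected {image_size}x{image_size}, "
                             f"got {pix.shape}")
        stem = f.stem
        patient_id = stem.rsplit("_", 1)[0]
        records.append(ImageRecord(patient_id=patient_id, image_id=stem,
                                   pixels=pix))
    return records


def load_dicom_dir(path: str | Path, image_size: int | None = None,
                   ) -> list[ImageRecord]:
    """Read a directory of single-frame DICOM slices under the PNG contract.

    The patient id is taken from the PatientID tag when present, otherwise
    from the file stem as for PNG inputs.
    """
    import pydicom

    path = Path(path)
    records = []
    for f in sorted(path.glob("*.dcm")):
        ds = pydicom.dcmread(f)
        pix = np.asarray(ds.pixel_array, dtype=float)
        if image_size is not None and pix.shape != (image_size, image_size):
            raise ValueError(f"{f.name}: expected {image_size}x{image_size}, "
                             f"got {pix.shape}")
        patient_id = str(getattr(ds, "PatientID", "") or f.stem.rsplit("_", 1)[0])
        records.append(ImageRecord(patient_id=patient_id, image_id=f.stem,
                                   pixels=pix))
    return records
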