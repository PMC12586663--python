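"""NIfTI and table I/O plus midsagittal slice extraction.

Volumes are assumed to be registered to a 1 mm standard grid already
(registration is upstream and out of scope).  Extraction reorients the
volume to nibabel's closest-canonical RAS+ order and takes the sagittal
plane at ``nx // 2``, re-expressed in the package's canonical 2D frame
(rows inferior->superior, columns anterior->posterior).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import FRAME_TAG, BinaryMask2D, MidsagittalSlice
from .morphometry import ShapeRecord


@dataclass
class VolumeImage:
    """A 3D scalar volume with its voxel->mm affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.affine is None:
            raise ValueError(
                "volume lacks orientation metadata (no affine); provide a "
                "canonical volume registered to standard space"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 voxel->mm map")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI volume (2D single slices are promoted to 3D)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt file
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis, :, :]
    elif data.ndim == 4:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 2D/3D image, got {data.ndim}D")
    return VolumeImage(data, img.affine)


def extract_midsagittal(vol: VolumeImage | MidsagittalSlice) -> MidsagittalSlice:
    """Sagittal slice at the left-right midline, in the canonical frame.

    The volume is reoriented to RAS+ axis order first, the slice taken
    at ``x = nx // 2``, and re-indexed so rows run inferior->superior
    and columns anterior->posterior.  Applying this to a slice is the
    identity.
    """
    if isinstance(vol, MidsagittalSlice):
        return vol
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), vol.affine)
    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj)
    x_mid = data.shape[0] // 2
    sag = data[x_mid]  # (y: P->A, z: I->S)
    pixels = sag.T[:, ::-1]  # rows = z (I->S), cols = flipped y (A->P)
    voxel_size = float(np.sqrt((canonical.affine[:3, :3] ** 2).sum(axis=0))[1])
    return MidsagittalSlice(np.ascontiguousarray(pixels), pixel_size_mm=voxel_size)


def _slice_affine(pixel_size_mm: float) -> np.ndarray:
    return np.diag([pixel_size_mm, pixel_size_mm, pixel_size_mm, 1.0])


def write_slice(sl: MidsagittalSlice, path: str | Path) -> None:
    """Write a 2D slice as a single-slice NIfTI."""
    nib.save(
        nib.Nifti1Image(sl.pixels.astype(np.float64), _slice_affine(sl.pixel_size_mm)),
        str(path),
    )


def write_mask(mask: BinaryMask2D, path: str | Path) -> None:
    """Write a 2D binary mask as a single-slice NIfTI (uint8)."""
    nib.save(
        nib.Nifti1Image(mask.pixels.astype(np.uint8), _slice_affine(mask.pixel_size_mm)),
        str(path),
    )


def read_mask(path: str | Path) -> BinaryMask2D:
    """Read a 2D (or singleton-3D) NIfTI as a binary mask."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise IOError(f"{path}: expected a 2D mask, got shape {data.shape}")
    voxel_size = float(np.sqrt((img.affine[:3, :3] ** 2).sum(axis=0))[0])
    return BinaryMask2D((data > 0.5).astype(np.uint8), pixel_size_mm=voxel_size)


def write_labels(labels: np.ndarray, path: str | Path, pixel_size_mm: float = 1.0) -> None:
    """Write an integer label image (e.g. Witelson codes 1-5) as NIfTI."""
    nib.save(
        nib.Nifti1Image(labels.astype(np.int16), _slice_affine(pixel_size_mm)), str(path)
    )


def write_png(sl: MidsagittalSlice | BinaryMask2D, path: str | Path) -> None:
    """Write a slice or mask as an 8-bit grayscale PNG (for quick looks)."""
    from PIL import Image

    arr = sl.pixels.astype(float)
    rng_ = arr.max() - arr.min()
    scaled = (arr - arr.min()) / rng_ if rng_ > 0 else np.zeros_like(arr)
    # flip rows so "superior" renders at the top of the PNG
    Image.fromarray((scaled[::-1] * 255).astype(np.uint8)).save(str(path))


def roundtrip_mask(mask: BinaryMask2D, path: str | Path) -> BinaryMask2D:
    """Write a mask to NIfTI and read it back (lossless by contract)."""
    write_mask(mask, path)
    return read_mask(path)


def write_metrics_table(records: list[ShapeRecord], path: str | Path) -> None:
    """Write shape records as a TSV with a fixed column order."""
    cols = ["subject_id"] + list(ShapeRecord.METRIC_FIELDS) + ["valid"]
    if any(r.qc_label is not None for r in records):
        cols += ["qc_label", "qc_votes"]
    df = pd.DataFrame([r.to_dict() for r in records])
    df = df.reindex(columns=cols)
    df.to_csv(path, sep="\t", index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read METAL-style tab-delimited summary statistics."""
    df = pd.read_csv(path, sep="\t")
    required = {"SNP", "A1", "A2", "BETA", "SE"}
    missing = required - set(df.columns)
    if missing:
        raise IOError(f"{path}: summary statistics missing columns {sorted(missing)}")
    return df


def read_correlation_matrix(path: str | Path) -> np.ndarray:
    """Read a trait-trait correlation matrix from delimited text.

    Accepts plain whitespace/tab/comma-delimited numeric text, with or
    without a header row of trait names.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = pd.read_csv(path, sep=None, engine="python")
        df = df.select_dtypes(include=[np.number])
    mat = df.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise IOError(f"{path}: correlation matrix must be square, got {mat.shape}")
    return mat
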