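"""Core 2D containers used throughout the pipeline.

Everything downstream of volume I/O works in a fixed anatomical frame:
rows index inferior -> superior and columns index anterior -> posterior,
so the genu of the corpus callosum sits at low column indices and the
splenium at high ones, and "thickness" is a per-column vertical extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical anatomical frame tag carried by every slice and mask.
FRAME_TAG = "rows=inferior->superior,cols=anterior->posterior"


@dataclass
class MidsagittalSlice:
    """A 2D grayscale midsagittal section in the canonical frame.

    Parameters
    ----------
    pixels : ndarray
        2D float array of image intensities.
    pixel_size_mm : float
        Isotropic in-plane pixel size in millimetres (1.0 for data on a
        1 mm standard grid).
    frame : str
        Anatomical frame declaration; must equal :data:`FRAME_TAG`.
    """

    pixels: np.ndarray
    pixel_size_mm: float = 1.0
    frame: str = FRAME_TAG

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice must be 2D, got shape {self.pixels.shape}")
        if not self.frame:
            raise ValueError("slice is missing its anatomical frame tag")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask2D:
    """A 2D binary corpus-callosum mask in the canonical frame.

    Pixel values are exactly {0, 1}; anything produced by thresholding a
    probability map at 0.5 fits this contract.
    """

    pixels: np.ndarray
    pixel_size_mm: float = 1.0
    frame: str = FRAME_TAG

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be exactly {0, 1}")
        self.pixels = arr.astype(np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.pixels.shape}")
        if not self.frame:
            raise ValueError("mask is missing its anatomical frame tag")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_pixels(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return self.area_pixels == 0

    def copy(self) -> "BinaryMask2D":
        return BinaryMask2D(self.pixels.copy(), self.pixel_size_mm, self.frame)
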