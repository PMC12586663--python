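import numpy as np
import pytest

from ccmorph.core import BinaryMask2D, MidsagittalSlice
from ccmorph.phantoms import PhantomSpec, make_cc_phantom, sample_spec


def make_band_mask(
    n_rows: int = 64,
    n_cols: int = 64,
    row0: int = 20,
    height: int = 6,
    col0: int = 10,
    width: int = 30,
    pixel_size_mm: float = 1.0,
) -> BinaryMask2D:
    """Axis-aligned rectangular band: the hand-checkable degenerate CC."""
    px = np.zeros((n_rows, n_cols), dtype=np.uint8)
    px[row0 : row0 + height, col0 : col0 + width] = 1
    return BinaryMask2D(px, pixel_size_mm)


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom image/mask pair (seed 0 default spec)."""
    return make_cc_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_masks():
    """Twenty varied phantom masks for invariant checks."""
    rng = np.random.default_rng(2024)
    return [make_cc_phantom(sample_spec(rng))[1] for _ in range(20)]


@pytest.fixture()
def band_mask():
    return make_band_mask()
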