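"""Synthetic midsagittal corpus-callosum phantoms and cohort simulators.

Everything the rest of the package needs to be exercised without real
scans lives here: arch-shaped single-component CC masks with smoothly
varying thickness, grayscale images with background clutter and noise,
the training-set augmentations (down/upsampling, 15-degree rotations,
occlusion boxes imitating partial agenesis), pass/fail corruptions for
the QC classifier, and a two-cohort GWAS summary-statistics simulator
with controllable between-cohort heterogeneity.

The phantom centerline is a quadratic Bezier arch through three control
points; the mask is the set of pixels within a half-thickness envelope
of that curve, where the half-thickness varies along the arc to give
the genu and splenium their characteristic bulbs.  Foreground intensity
is 1.0 on a 0.0 background with additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform

from .assoc_stats import StudyEffect
from .core import BinaryMask2D, MidsagittalSlice
from .morphometry import ShapeRecord, shape_record

#: Non-strand-ambiguous allele pairs used by the cohort simulator.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))

#: Corruption modes understood by :func:`degrade_mask`.
CORRUPTION_MODES = ("holes", "truncation", "leak_blob", "empty", "split")

#: Four-connectivity structuring element for component checks.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic CC arch.

    ``centerline_controls`` are three (row, col) control points of a
    quadratic Bezier in the canonical frame (rows inferior->superior,
    columns anterior->posterior); the middle point pulls the arch
    upward.  The half-thickness along arc parameter t in [0, 1] is
    ``base + amplitude * (1 + cos(2 pi t)) / 2`` so the ends (genu,
    splenium) are thicker than the midbody.
    """

    grid_shape: tuple[int, int] = (64, 64)
    centerline_controls: tuple[tuple[float, float], ...] = (
        (24.0, 8.0),
        (56.0, 32.0),
        (22.0, 56.0),
    )
    base_half_thickness: float = 2.5
    amplitude: float = 1.5
    noise_sd: float = 0.1
    background_blob_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 64 or self.grid_shape[1] < 64:
            raise ValueError("grid_shape must be at least (64, 64)")
        if self.base_half_thickness < 1.0:
            raise ValueError("base half-thickness must be >= 1 pixel")
        if len(self.centerline_controls) != 3:
            raise ValueError("the arch needs exactly 3 control points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class AugmentParams:
    """Training-set augmentation: resample, rotate, occlude."""

    resample_factor: int | None = None
    rotation_deg: int = 0
    occlusion_boxes: int = 0
    box_size_range: tuple[int, int] = (6, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resample_factor is not None and self.resample_factor not in (2, 3, 4, 5):
            raise ValueError("resample_factor must be one of {2, 3, 4, 5}")
        if self.rotation_deg % 15 != 0:
            raise ValueError("rotation must be a multiple of 15 degrees")
        if self.occlusion_boxes < 0:
            raise ValueError("occlusion_boxes must be nonnegative")


@dataclass
class CorruptionMode:
    """A QC-failure corruption: which defect, how severe, which seed."""

    mode: str
    severity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in CORRUPTION_MODES:
            raise ValueError(
                f"unknown corruption mode {self.mode!r}; choose from {CORRUPTION_MODES}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")


def _bezier(controls, t: np.ndarray) -> np.ndarray:
    """Quadratic Bezier points, shape (len(t), 2) in (row, col)."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in controls)
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _half_thickness(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    return spec.base_half_thickness + spec.amplitude * (1 + np.cos(2 * np.pi * t)) / 2


def rasterize_arch(spec: PhantomSpec, n_samples: int = 600) -> np.ndarray:
    """Binary envelope of the arch: pixels within half-thickness of the curve.

    The curve is approximated by a dense polyline; a pixel is foreground
    when its exact distance to some segment is at most the half-thickness
    interpolated at the closest point, so constant-thickness straight
    arches rasterize to exact bands.
    """
    rows, cols = spec.grid_shape
    t = np.linspace(0.0, 1.0, n_samples)
    pts = _bezier(spec.centerline_controls, t)  # (n, 2)
    half = _half_thickness(spec, t)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)  # (P, 2)
    inside = np.zeros(pix.shape[0], dtype=bool)
    a, b = pts[:-1], pts[1:]
    ha, hb = half[:-1], half[1:]
    ab = b - a
    ab_len2 = np.maximum((ab**2).sum(axis=1), 1e-30)
    # chunk over segments to bound memory
    for start in range(0, a.shape[0], 128):
        sl = slice(start, start + 128)
        diff = pix[:, None, :] - a[None, sl, :]  # (P, S, 2)
        s = np.clip(
            (diff * ab[None, sl, :]).sum(axis=2) / ab_len2[None, sl], 0.0, 1.0
        )
        closest = a[None, sl, :] + s[:, :, None] * ab[None, sl, :]
        d = np.sqrt(((pix[:, None, :] - closest) ** 2).sum(axis=2))
        h = ha[None, sl] + s * (hb - ha)[None, sl]
        inside |= (d <= h + 1e-9).any(axis=1)
    return inside.reshape(rows, cols).astype(np.uint8)


def make_cc_phantom(spec: PhantomSpec) -> tuple[MidsagittalSlice, BinaryMask2D]:
    """Generate one phantom image/mask pair.

    The mask is the rasterized arch envelope; the image is mask
    foreground at intensity 1.0 plus background blobs (intensity 0.5)
    and Gaussian noise of ``spec.noise_sd``.  The same seed reproduces
    the output bit for bit.  An arch whose envelope reaches the grid
    border is rejected with a sizing error.
    """
    pixels = rasterize_arch(spec)
    if pixels.sum() == 0:
        raise ValueError("phantom arch rasterized to an empty mask")
    border = (
        pixels[0, :].any()
        or pixels[-1, :].any()
        or pixels[:, 0].any()
        or pixels[:, -1].any()
    )
    if border:
        raise ValueError(
            "phantom arch exceeds the grid: envelope touches the image border; "
            "enlarge grid_shape or shrink the arch"
        )
    n_comp = ndimage.label(pixels, structure=_CROSS)[1]
    if n_comp != 1:
        raise ValueError(f"phantom mask has {n_comp} components; expected 1")

    rng = np.random.default_rng(spec.seed)
    image = pixels.astype(float).copy()
    rows, cols = spec.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    for _ in range(spec.background_blob_count):
        cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
        radius = rng.uniform(2.0, 5.0)
        blob = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
        image = np.where((blob) & (pixels == 0), 0.5, image)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return (
        MidsagittalSlice(image),
        BinaryMask2D(pixels),
    )


def sample_spec(rng: np.random.Generator, grid_shape=(64, 64)) -> PhantomSpec:
    """Draw a randomized but always-in-grid phantom spec.

    Control points and thickness are jittered around the default arch
    (scaled to ``grid_shape``) within ranges chosen so the envelope
    never reaches the border; used to build varied training/QC sets.
    """
    sr = grid_shape[0] / 64.0
    sc = grid_shape[1] / 64.0
    p0 = (rng.uniform(20, 28) * sr, rng.uniform(6, 10) * sc)
    p1 = (rng.uniform(52, 60) * sr, rng.uniform(28, 36) * sc)
    p2 = (rng.uniform(18, 26) * sr, rng.uniform(54, 58) * sc)
    base = rng.uniform(2.0, 3.2)
    amplitude = rng.uniform(0.5, min(1.8, 4.5 - base))
    return PhantomSpec(
        grid_shape=grid_shape,
        centerline_controls=(p0, p1, p2),
        base_half_thickness=base,
        amplitude=amplitude,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def degrade_mask(mask: BinaryMask2D, corruption: CorruptionMode) -> BinaryMask2D:
    """Return a corrupted copy of the mask; the input is never modified.

    Modes: ``holes`` knocks out a severity-fraction of interior pixels;
    ``truncation`` removes the posterior severity-fraction of occupied
    columns; ``leak_blob`` attaches a spurious blob near the mask;
    ``empty`` zeroes everything; ``split`` removes a central column band
    wide enough to disconnect the arch.
    """
    if corruption.mode != "empty" and mask.is_empty():
        raise ValueError("cannot degrade an empty mask (except mode='empty')")
    rng = np.random.default_rng(corruption.seed)
    out = mask.pixels.copy()
    sev = corruption.severity

    if corruption.mode == "empty":
        out[:] = 0
    elif corruption.mode == "holes":
        interior = ndimage.binary_erosion(out.astype(bool), structure=_CROSS)
        idx = np.flatnonzero(interior.ravel())
        n_remove = int(round(sev * idx.size))
        if n_remove > 0:
            chosen = rng.choice(idx, size=n_remove, replace=False)
            out.ravel()[chosen] = 0
    elif corruption.mode == "truncation":
        cols = np.flatnonzero(out.any(axis=0))
        n_remove = int(round(sev * cols.size))
        if n_remove > 0:
            out[:, cols[cols.size - n_remove :]] = 0
    elif corruption.mode == "leak_blob":
        boundary = out.astype(bool) & ~ndimage.binary_erosion(
            out.astype(bool), structure=_CROSS
        )
        ridx = rng.integers(0, np.count_nonzero(boundary))
        br, bc = np.argwhere(boundary)[ridx]
        radius = max(2.0, sev * 8.0)
        angle = rng.uniform(0, 2 * np.pi)
        cy = br + 1.5 * radius * math.sin(angle)
        cx = bc + 1.5 * radius * math.cos(angle)
        rr, cc = np.meshgrid(
            np.arange(out.shape[0]), np.arange(out.shape[1]), indexing="ij"
        )
        out[(rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2] = 1
    elif corruption.mode == "split":
        cols = np.flatnonzero(out.any(axis=0))
        width = int(round(sev * cols.size / 2.0))
        if width > 0:
            mid = cols.size // 2
            lo = max(0, mid - width // 2)
            out[:, cols[lo : lo + width]] = 0
    return BinaryMask2D(out, mask.pixel_size_mm, mask.frame)


def augment_image(image: MidsagittalSlice, params: AugmentParams) -> MidsagittalSlice:
    """Apply the training augmentations: resample, rotate, occlude.

    Down-then-upsampling restores the original pixel dimensions, so the
    output always matches the input shape.  Rotation is restricted to
    multiples of 15 degrees.  Occlusion boxes are set to the image
    minimum, imitating missing tissue (partial agenesis).
    """
    rng = np.random.default_rng(params.seed)
    out = image.pixels.astype(float)
    shape = out.shape
    if params.resample_factor is not None:
        f = params.resample_factor
        small = transform.resize(
            out,
            (max(1, shape[0] // f), max(1, shape[1] // f)),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        )
        out = transform.resize(small, shape, order=1, preserve_range=True)
    if params.rotation_deg % 360 != 0:
        out = transform.rotate(
            out, params.rotation_deg, preserve_range=True, mode="constant", cval=float(out.min())
        )
    lo = float(out.min())
    for _ in range(params.occlusion_boxes):
        bh = int(rng.integers(params.box_size_range[0], params.box_size_range[1] + 1))
        bw = int(rng.integers(params.box_size_range[0], params.box_size_range[1] + 1))
        r0 = int(rng.integers(0, max(1, shape[0] - bh)))
        c0 = int(rng.integers(0, max(1, shape[1] - bw)))
        out[r0 : r0 + bh, c0 : c0 + bw] = lo
    return MidsagittalSlice(out, image.pixel_size_mm, image.frame)


def make_qc_dataset(
    n_pass: int,
    n_fail: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[ShapeRecord, str]]:
    """Labeled shape records for QC training: intact vs corrupted phantoms.

    Pass records are morphometry on intact phantom masks (specs jittered
    per record around the given base spec); fail records are morphometry
    on the same kind of masks after a cycling corruption (holes,
    truncation, leak_blob, empty, split) at severities in [0.3, 0.8].
    """
    if n_pass < 1 or n_fail < 1:
        raise ValueError("need at least one record of each class")
    base = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    records: list[tuple[ShapeRecord, str]] = []
    for i in range(n_pass):
        s = sample_spec(rng, base.grid_shape)
        _, mask = make_cc_phantom(s)
        records.append((shape_record(mask, f"pass_{i:04d}"), "pass"))
    for i in range(n_fail):
        s = sample_spec(rng, base.grid_shape)
        _, mask = make_cc_phantom(s)
        corruption = CorruptionMode(
            mode=CORRUPTION_MODES[i % len(CORRUPTION_MODES)],
            severity=float(rng.uniform(0.3, 0.8)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bad = degrade_mask(mask, corruption)
        records.append((shape_record(bad, f"fail_{i:04d}"), "fail"))
    return records


def qc_dataset_to_frame(records: list[tuple[ShapeRecord, str]]) -> pd.DataFrame:
    """Tab-friendly table of a QC dataset (one row per record + label)."""
    rows = []
    for rec, label in records:
        d = rec.to_dict()
        d["label"] = label
        rows.append(d)
    return pd.DataFrame(rows)


def make_cohort_effects(
    m_variants: int,
    n1: int,
    n2: int,
    tau2_true: float,
    seed: int = 0,
    beta_sd: float = 0.0,
    sigma_y: float = 1.0,
) -> tuple[list[StudyEffect], list[StudyEffect]]:
    """Simulate two cohorts' GWAS summary statistics for the same variants.

    Per variant, a true effect is drawn once (N(0, beta_sd^2); 0 by
    default, the null); each cohort observes it plus a between-cohort
    deviation of variance ``tau2_true`` plus sampling noise with
    standard error ``sigma_y / sqrt(2 p q n)``, the usual per-allele
    GWAS scaling.  Allele frequencies are uniform on (0.01, 0.99) and
    shared; alleles are drawn from non-strand-ambiguous pairs.
    """
    if m_variants < 1:
        raise ValueError("need at least one variant")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cohort sample sizes must be positive")
    if tau2_true < 0:
        raise ValueError("tau2_true must be nonnegative")
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.01, 0.99, m_variants)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m_variants)
    beta_true = (
        rng.normal(0.0, beta_sd, m_variants) if beta_sd > 0 else np.zeros(m_variants)
    )
    cohorts = []
    for n in (n1, n2):
        se = sigma_y / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
        dev = (
            rng.normal(0.0, math.sqrt(tau2_true), m_variants)
            if tau2_true > 0
            else np.zeros(m_variants)
        )
        beta_obs = beta_true + dev + rng.normal(0.0, 1.0, m_variants) * se
        cohorts.append(
            [
                StudyEffect(
                    f"rs{j:07d}",
                    _ALLELE_PAIRS[pair_idx[j]][0],
                    _ALLELE_PAIRS[pair_idx[j]][1],
                    float(eaf[j]),
                    float(beta_obs[j]),
                    float(se[j]),
                    n,
                )
                for j in range(m_variants)
            ]
        )
    return cohorts[0], cohorts[1]
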