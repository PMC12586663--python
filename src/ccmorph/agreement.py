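"""Segmentation agreement and test-retest reliability statistics.

Dice overlap between binary masks and the intraclass correlation
coefficient (ICC) for repeated-measure metric tables.  The default ICC
is the two-way mixed-effects, consistency, single-measure form ICC(3,1)
computed from the two-way ANOVA decomposition; ICC(2,1) (absolute
agreement) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask2D


def dice(a: BinaryMask2D | np.ndarray, b: BinaryMask2D | np.ndarray) -> float:
    """Dice overlap coefficient 2|A n B| / (|A| + |B|); 1.0 when both empty."""
    pa = a.pixels if isinstance(a, BinaryMask2D) else np.asarray(a)
    pb = b.pixels if isinstance(b, BinaryMask2D) else np.asarray(b)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    pa, pb = pa.astype(bool), pb.astype(bool)
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pa, pb).sum() / denom)


@dataclass
class RetestMatrix:
    """Subjects x sessions matrix of one shape metric."""

    values: np.ndarray
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("retest matrix must be 2D (subjects x sessions)")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 sessions")
        if not np.isfinite(self.values).all():
            raise ValueError("missing or non-finite entries are not allowed")


class ZeroVarianceError(ValueError):
    """Raised when between-subject variance is zero and ICC is undefined."""


def icc_test_retest(m: RetestMatrix | np.ndarray, form: str = "ICC3") -> float:
    """Single-measure intraclass correlation from a retest matrix.

    ``form='ICC3'`` (default): two-way mixed effects, consistency,
    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E), where MS_R is the
    between-subject mean square and MS_E the residual mean square of the
    two-way (subject x session) ANOVA.  ``form='ICC2'`` gives the
    two-way random-effects absolute-agreement ICC(2,1), which also
    charges systematic session differences against reliability.
    Estimates are truncated below at -1.
    """
    if not isinstance(m, RetestMatrix):
        m = RetestMatrix(np.asarray(m))
    if form not in ("ICC3", "ICC2"):
        raise ValueError("form must be 'ICC3' or 'ICC2'")
    y = m.values
    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    sess_means = y.mean(axis=0)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((sess_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0 or (ms_r + (k - 1) * ms_e) == 0:
        raise ZeroVarianceError("no between-subject variance; ICC undefined")
    if form == "ICC3":
        val = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    else:
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
        if denom == 0:
            raise ZeroVarianceError("degenerate ANOVA decomposition; ICC undefined")
        val = (ms_r - ms_e) / denom
    return float(max(val, -1.0))
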