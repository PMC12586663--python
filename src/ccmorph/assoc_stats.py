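"""Association statistics for GWAS summary data.

The arithmetic layer behind the morphometry GWAS: DerSimonian-Laird
random-effects meta-analysis of per-variant effects across cohorts,
per-variant variance explained (R^2 = 2pq beta^2 / sigma_y^2), the
Li-Ji eigenvalue-based effective number of independent tests with its
Bonferroni threshold, the Szymkiewicz-Simpson overlap coefficient, and
cross-cohort confidence-interval / sign concordance.

All estimators here are implemented from their defining formulas; no
external meta-analysis engine is called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Strand-ambiguous allele pairs that cannot be safely flipped.
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: METAL-style summary-statistics column order.
SUMSTATS_COLUMNS = ["SNP", "A1", "A2", "FREQ", "BETA", "SE", "N"]


@dataclass
class StudyEffect:
    """One variant's association result in one cohort.

    ``beta`` is the per-allele effect of ``effect_allele`` in trait
    units; ``eaf`` its frequency; ``se`` the standard error; ``n`` the
    cohort sample size.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.variant_id}: EAF must be in (0, 1)")
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: SE must be positive")
        if self.n <= 0:
            raise ValueError(f"{self.variant_id}: sample size must be positive")

    def is_strand_ambiguous(self) -> bool:
        return (self.effect_allele, self.other_allele) in AMBIGUOUS_PAIRS


@dataclass
class MetaEffect:
    """Pooled DerSimonian-Laird result for one variant."""

    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    q_stat: float
    tau2: float
    k: int
    direction: str

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if self.k < 2:
            raise ValueError("meta-analysis needs k >= 2 studies")


class AlleleMismatchError(ValueError):
    """Raised when study alleles cannot be reconciled."""


def align_effect(ref: StudyEffect, other: StudyEffect) -> StudyEffect:
    """Align ``other`` to the effect allele of ``ref``.

    Matching alleles pass through; swapped alleles flip the beta sign
    and the allele frequency.  Anything else (including the attempt to
    reconcile via alleles that differ) raises, listing the variant.
    Strand-ambiguous variants are accepted when alleles match literally
    but are flagged by :meth:`StudyEffect.is_strand_ambiguous`.
    """
    if other.variant_id != ref.variant_id:
        raise AlleleMismatchError(
            f"variant id mismatch: {ref.variant_id} vs {other.variant_id}"
        )
    if (other.effect_allele, other.other_allele) == (
        ref.effect_allele,
        ref.other_allele,
    ):
        return other
    if (other.effect_allele, other.other_allele) == (
        ref.other_allele,
        ref.effect_allele,
    ):
        return StudyEffect(
            other.variant_id,
            ref.effect_allele,
            ref.other_allele,
            1.0 - other.eaf,
            -other.beta,
            other.se,
            other.n,
        )
    raise AlleleMismatchError(
        f"{ref.variant_id}: alleles {other.effect_allele}/{other.other_allele} "
        f"cannot be aligned to {ref.effect_allele}/{ref.other_allele}"
    )


def _dl_arrays(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, float, float]:
    """Core DL pooling on aligned arrays -> (beta*, se*, Q, tau2)."""
    w = 1.0 / ses**2
    beta_fe = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - beta_fe) ** 2))
    k = betas.size
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta_re = float(np.sum(w_star * betas) / np.sum(w_star))
    se_re = float(1.0 / math.sqrt(np.sum(w_star)))
    return beta_re, se_re, q, tau2


def dl_meta(effects: list[StudyEffect]) -> MetaEffect:
    """DerSimonian-Laird random-effects meta-analysis of one variant.

    Studies are aligned to the first study's effect allele (signs
    flipped for swapped alleles).  Weights are inverse-variance; the
    between-study variance is the moment estimator
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` and the
    pooled effect re-weights by ``1/(se^2 + tau2)``.  The p-value is the
    two-sided normal tail of z = beta*/se*.
    """
    if len(effects) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    ref = effects[0]
    aligned = [ref] + [align_effect(ref, e) for e in effects[1:]]
    betas = np.array([e.beta for e in aligned])
    ses = np.array([e.se for e in aligned])
    beta_re, se_re, q, tau2 = _dl_arrays(betas, ses)
    z = beta_re / se_re
    p = 2.0 * stats.norm.sf(abs(z))
    direction = "".join("+" if b >= 0 else "-" for b in betas)
    return MetaEffect(
        ref.variant_id, beta_re, se_re, z, float(max(p, np.finfo(float).tiny)),
        q, tau2, len(aligned), direction,
    )


def dl_meta_table(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Vectorized DL meta-analysis over METAL-style cohort tables.

    Each table must carry :data:`SUMSTATS_COLUMNS`; variants are matched
    on SNP id, alleles aligned to the first cohort (swapped alleles flip
    beta and FREQ), and one pooled row is produced per variant with
    columns BETA_RE, SE_RE, Z, P_RE, Q, TAU2, DIRECTION.
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis needs at least 2 cohorts")
    ref = tables[0].set_index("SNP")
    betas = [ref["BETA"].to_numpy(float)]
    k = len(tables)
    ses = [ref["SE"].to_numpy(float)]
    for t in tables[1:]:
        t = t.set_index("SNP")
        missing = ref.index.difference(t.index)
        if len(missing):
            raise AlleleMismatchError(
                f"variants absent from a cohort: {list(missing[:5])}..."
            )
        t = t.loc[ref.index]
        same = (t["A1"] == ref["A1"]) & (t["A2"] == ref["A2"])
        swapped = (t["A1"] == ref["A2"]) & (t["A2"] == ref["A1"])
        bad = ~(same | swapped)
        if bad.any():
            raise AlleleMismatchError(
                f"unalignable alleles for: {list(ref.index[bad][:5])}"
            )
        sign = np.where(same, 1.0, -1.0)
        betas.append(sign * t["BETA"].to_numpy(float))
        ses.append(t["SE"].to_numpy(float))
    b = np.vstack(betas)  # k x m
    s = np.vstack(ses)
    w = 1.0 / s**2
    sw = w.sum(axis=0)
    beta_fe = (w * b).sum(axis=0) / sw
    q = (w * (b - beta_fe) ** 2).sum(axis=0)
    denom = sw - (w**2).sum(axis=0) / sw
    tau2 = np.maximum(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (s**2 + tau2)
    beta_re = (w_star * b).sum(axis=0) / w_star.sum(axis=0)
    se_re = 1.0 / np.sqrt(w_star.sum(axis=0))
    z = beta_re / se_re
    p = 2.0 * stats.norm.sf(np.abs(z))
    direction = ["".join("+" if x >= 0 else "-" for x in b[:, j]) for j in range(b.shape[1])]
    return pd.DataFrame(
        {
            "SNP": ref.index,
            "BETA_RE": beta_re,
            "SE_RE": se_re,
            "Z": z,
            "P_RE": np.maximum(p, np.finfo(float).tiny),
            "Q": q,
            "TAU2": tau2,
            "DIRECTION": direction,
        }
    ).reset_index(drop=True)


def variance_explained(beta: float, eaf: float, var_y: float) -> float:
    """Per-variant variance explained: R^2 = 2 p q beta^2 / sigma_y^2."""
    if not (np.isfinite(beta) and np.isfinite(eaf) and np.isfinite(var_y)):
        raise ValueError("inputs must be finite")
    if not 0.0 < eaf < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    if var_y <= 0:
        raise ValueError("trait variance must be positive")
    return 2.0 * eaf * (1.0 - eaf) * beta**2 / var_y


def effective_tests(corr: np.ndarray) -> float:
    """Li-Ji effective number of independent tests from a correlation matrix.

    M_eff = sum_i f(|lambda_i|) with f(x) = I(x >= 1) + (x - floor(x)),
    over the eigenvalues of the trait-trait correlation matrix.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.abs(np.linalg.eigvalsh(corr))
    # snap eigenvalues that are integers up to numerical noise, so the
    # fractional part f(x) = x - floor(x) does not read 0.999... as ~1
    near = np.round(lam)
    lam = np.where(np.abs(lam - near) < 1e-9 * max(1.0, corr.shape[0]), near, lam)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def bonferroni_threshold(alpha: float, m_eff: float) -> float:
    """Multiple-testing threshold alpha / M_eff."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m_eff < 1.0:
        raise ValueError("effective test count must be >= 1")
    return alpha / m_eff


def overlap_coefficient(a: set, b: set) -> float:
    """Szymkiewicz-Simpson overlap: |A n B| / min(|A|, |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap coefficient needs two nonempty sets")
    return len(a & b) / min(len(a), len(b))


@dataclass
class ConcordanceResult:
    """Cross-cohort effect-size agreement summary."""

    n_variants: int
    n_within_ci: int
    fraction_within_ci: float
    n_sign_consistent: int

    @property
    def percent_within_ci(self) -> int:
        """Fraction within CI as the nearest integer percent."""
        return round(100.0 * self.fraction_within_ci)


def ci_concordance(
    primary: list[StudyEffect],
    replication: list[StudyEffect],
    level: float = 0.95,
) -> ConcordanceResult:
    """Effect-size concordance between a primary and a replication cohort.

    A variant is concordant when the primary beta falls inside the
    replication's ``level`` confidence interval ``repl beta +/- z * repl
    se``.  Sign consistency counts variants whose aligned betas share a
    sign across both cohorts.
    """
    prim = {e.variant_id: e for e in primary}
    repl = {e.variant_id: e for e in replication}
    unmatched = sorted(set(prim) ^ set(repl))
    if unmatched:
        raise ValueError(f"unmatched variants: {unmatched[:10]}")
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    n_in, n_sign = 0, 0
    for vid, p_eff in prim.items():
        r_eff = align_effect(p_eff, repl[vid])
        lo = r_eff.beta - zcrit * r_eff.se
        hi = r_eff.beta + zcrit * r_eff.se
        if lo <= p_eff.beta <= hi:
            n_in += 1
        if math.copysign(1.0, p_eff.beta) == math.copysign(1.0, r_eff.beta):
            n_sign += 1
    n = len(prim)
    return ConcordanceResult(n, n_in, n_in / n, n_sign)


def effects_to_frame(effects: list[StudyEffect]) -> pd.DataFrame:
    """METAL-style summary-statistics table (SNP A1 A2 FREQ BETA SE N)."""
    return pd.DataFrame(
        [
            {
                "SNP": e.variant_id,
                "A1": e.effect_allele,
                "A2": e.other_allele,
                "FREQ": e.eaf,
                "BETA": e.beta,
                "SE": e.se,
                "N": e.n,
            }
            for e in effects
        ],
        columns=SUMSTATS_COLUMNS,
    )


def frame_to_effects(df: pd.DataFrame) -> list[StudyEffect]:
    """Parse a METAL-style table back into study effects."""
    return [
        StudyEffect(str(r.SNP), str(r.A1), str(r.A2), float(r.FREQ), float(r.BETA), float(r.SE), int(r.N))
        for r in df.itertuples(index=False)
    ]
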