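import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccmorph.assoc_stats import (
    AlleleMismatchError,
    StudyEffect,
    align_effect,
    bonferroni_threshold,
    ci_concordance,
    dl_meta,
    dl_meta_table,
    effective_tests,
    effects_to_frame,
    frame_to_effects,
    overlap_coefficient,
    variance_explained,
)


def eff(vid="rs1", a1="A", a2="G", eaf=0.3, beta=0.1, se=0.05, n=1000):
    return StudyEffect(vid, a1, a2, eaf, beta, se, n)


class TestStudyEffect:
    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="EAF"):
            eff(eaf=0.0)
        with pytest.raises(ValueError, match="SE"):
            eff(se=0.0)
        with pytest.raises(ValueError, match="sample size"):
            eff(n=0)

    def test_strand_ambiguity_flag(self):
        assert eff(a1="A", a2="T").is_strand_ambiguous()
        assert eff(a1="C", a2="G").is_strand_ambiguous()
        assert not eff(a1="A", a2="G").is_strand_ambiguous()


class TestAlignEffect:
    def test_matching_alleles_pass_through(self):
        ref, other = eff(), eff(beta=0.2)
        assert align_effect(ref, other) is other

    def test_swapped_alleles_flip_beta_and_eaf(self):
        ref = eff(a1="A", a2="G")
        other = eff(a1="G", a2="A", eaf=0.7, beta=0.2)
        out = align_effect(ref, other)
        assert out.beta == -0.2
        assert out.eaf == pytest.approx(0.3)
        assert (out.effect_allele, out.other_allele) == ("A", "G")

    def test_unalignable_alleles_raise(self):
        with pytest.raises(AlleleMismatchError, match="rs1"):
            align_effect(eff(a1="A", a2="G"), eff(a1="A", a2="C"))

    def test_variant_id_mismatch_raises(self):
        with pytest.raises(AlleleMismatchError, match="mismatch"):
            align_effect(eff(vid="rs1"), eff(vid="rs2"))


class TestDlMeta:
    def test_identical_studies_recover_input(self):
        # k identical studies: Q=0, tau2=0, se* = se/sqrt(k)
        studies = [eff(beta=0.3, se=0.1) for _ in range(4)]
        m = dl_meta(studies)
        assert m.beta == pytest.approx(0.3)
        assert m.se == pytest.approx(0.1 / 2.0)
        assert m.q_stat == pytest.approx(0.0)
        assert m.tau2 == 0.0
        assert m.direction == "++++"

    def test_hand_worked_heterogeneous_pair(self):
        # betas (1, 0), se 0.1 both: w=100 each, beta_fe=0.5,
        # Q = 100*0.25*2 = 50, denom = 200 - 20000/200 = 100,
        # tau2 = (50-1)/100 = 0.49, w* = 1/0.5 = 2 each,
        # beta* = 0.5, se* = 1/sqrt(4) = 0.5
        m = dl_meta([eff(beta=1.0, se=0.1), eff(beta=0.0, se=0.1)])
        assert m.q_stat == pytest.approx(50.0)
        assert m.tau2 == pytest.approx(0.49)
        assert m.beta == pytest.approx(0.5)
        assert m.se == pytest.approx(0.5)
        assert m.p == pytest.approx(2 * stats.norm.sf(1.0))

    def test_tau2_truncated_at_zero(self):
        # nearly identical betas, Q < k-1 -> tau2 clamps to 0
        m = dl_meta([eff(beta=0.100, se=0.1), eff(beta=0.101, se=0.1)])
        assert m.tau2 == 0.0

    def test_alignment_inside_meta(self):
        ref = eff(a1="A", a2="G", beta=0.3)
        flipped = eff(a1="G", a2="A", eaf=0.7, beta=-0.3)
        m = dl_meta([ref, flipped])
        assert m.beta == pytest.approx(0.3)
        assert m.q_stat == pytest.approx(0.0)
        assert m.direction == "++"

    def test_single_study_rejected(self):
        with pytest.raises(ValueError, match="2 studies"):
            dl_meta([eff()])

    def test_matches_statsmodels_combine_effects(self):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        rng = np.random.default_rng(7)
        betas = rng.normal(0.1, 0.3, size=6)
        ses = rng.uniform(0.05, 0.4, size=6)
        ours = dl_meta(
            [eff(beta=float(b), se=float(s)) for b, s in zip(betas, ses)]
        )
        ref = sm_meta.combine_effects(betas, ses**2, method_re="dl")
        frame = ref.summary_frame()
        assert ours.beta == pytest.approx(frame.loc["random effect", "eff"], rel=1e-9)
        assert ours.tau2 == pytest.approx(float(ref.tau2), rel=1e-9)


class TestDlMetaTable:
    def _tables(self, k=3, m=40, seed=0):
        from ccmorph.phantoms import make_cohort_effects

        c1, c2 = make_cohort_effects(m, 3000, 5000, 0.05, seed=seed, beta_sd=0.2)
        tabs = [effects_to_frame(c1), effects_to_frame(c2)]
        if k == 3:
            _, c3 = make_cohort_effects(m, 3000, 4000, 0.05, seed=seed, beta_sd=0.2)
            tabs.append(effects_to_frame(c3))
        return tabs

    def test_matches_scalar_dl_meta_per_variant(self):
        tabs = self._tables(k=2)
        out = dl_meta_table(tabs)
        e1 = frame_to_effects(tabs[0])
        e2 = frame_to_effects(tabs[1])
        for i, (a, b) in enumerate(zip(e1, e2)):
            scalar = dl_meta([a, b])
            row = out.iloc[i]
            assert row.SNP == a.variant_id
            assert row.BETA_RE == pytest.approx(scalar.beta, rel=1e-12)
            assert row.SE_RE == pytest.approx(scalar.se, rel=1e-12)
            assert row.TAU2 == pytest.approx(scalar.tau2, rel=1e-12, abs=1e-15)
            assert row.P_RE == pytest.approx(scalar.p, rel=1e-9)
            assert row.DIRECTION == scalar.direction

    def test_swapped_alleles_in_one_cohort(self):
        tabs = self._tables(k=2)
        flipped = tabs[1].copy()
        flipped[["A1", "A2"]] = flipped[["A2", "A1"]].to_numpy()
        flipped["BETA"] = -flipped["BETA"]
        flipped["FREQ"] = 1.0 - flipped["FREQ"]
        assert np.allclose(
            dl_meta_table([tabs[0], flipped]).BETA_RE,
            dl_meta_table(tabs).BETA_RE,
        )

    def test_missing_variant_raises(self):
        tabs = self._tables(k=2)
        with pytest.raises(AlleleMismatchError, match="absent"):
            dl_meta_table([tabs[0], tabs[1].iloc[1:]])

    def test_roundtrip_frame_effects(self):
        effs = [eff(vid=f"rs{i}", beta=0.1 * i, eaf=0.2 + 0.01 * i) for i in range(5)]
        back = frame_to_effects(effects_to_frame(effs))
        assert all(
            a.variant_id == b.variant_id and a.beta == b.beta and a.eaf == b.eaf
            for a, b in zip(effs, back)
        )


class TestVarianceExplained:
    def test_hand_arithmetic(self):
        # 2 * 0.2 * 0.8 * 0.3^2 / 1.8 = 0.016
        assert variance_explained(0.3, 0.2, 1.8) == pytest.approx(0.016)

    def test_zero_beta_is_zero(self):
        assert variance_explained(0.0, 0.5, 1.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 1.0, 1.0)
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.5, 0.0)
        with pytest.raises(ValueError):
            variance_explained(math.nan, 0.5, 1.0)


class TestEffectiveTests:
    def test_identity_matrix_gives_m(self):
        for m in (1, 3, 11):
            assert effective_tests(np.eye(m)) == pytest.approx(float(m))

    def test_rank_one_gives_one(self):
        assert effective_tests(np.ones((6, 6))) == pytest.approx(1.0)

    def test_two_by_two_half_correlation(self):
        # eigenvalues 1.5 and 0.5 -> f(1.5)=1.5, f(0.5)=0.5 -> 2.0
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert effective_tests(corr) == pytest.approx(2.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            effective_tests(np.array([[1.0, 0.2], [0.5, 1.0]]))

    def test_meff_between_one_and_m(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 15))
        x[:, 1] = x[:, 0] + 0.1 * rng.normal(size=200)
        corr = np.corrcoef(x, rowvar=False)
        meff = effective_tests(corr)
        assert 1.0 <= meff <= 15.0


class TestBonferroniThreshold:
    def test_threshold_arithmetic(self):
        assert bonferroni_threshold(0.05, 10.0) == pytest.approx(5e-3)
        # genome-wide alpha over fractional effective tests
        assert f"{bonferroni_threshold(5e-8, 8.16):.3g}" == "6.13e-09"
        assert f"{bonferroni_threshold(5e-8, 11.0):.3g}" == "4.55e-09"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 5.0)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0.5)


class TestOverlapCoefficient:
    def test_subset_is_one(self):
        assert overlap_coefficient({1, 2}, {1, 2, 3, 4}) == 1.0

    def test_disjoint_is_zero(self):
        assert overlap_coefficient({1}, {2}) == 0.0

    def test_overlap_at_least_jaccard(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = set(rng.integers(0, 30, size=10).tolist())
            b = set(rng.integers(0, 30, size=10).tolist())
            if not (a and b):
                continue
            jaccard = len(a & b) / len(a | b)
            assert overlap_coefficient(a, b) >= jaccard

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {1})


class TestCiConcordance:
    def test_all_inside_wide_intervals(self):
        prim = [eff(vid=f"rs{i}", beta=0.1) for i in range(10)]
        repl = [eff(vid=f"rs{i}", beta=0.0, se=1.0) for i in range(10)]
        res = ci_concordance(prim, repl)
        assert res.n_within_ci == 10
        assert res.percent_within_ci == 100

    def test_known_counts_give_expected_percent(self):
        # 124 of 152 primary betas inside the replication 95% CI -> 82%
        prim, repl = [], []
        for i in range(152):
            beta = 1.0 if i < 124 else 3.0  # CI is [-1.96, 1.96]
            prim.append(eff(vid=f"v{i}", beta=beta, se=0.2))
            repl.append(eff(vid=f"v{i}", beta=0.0, se=1.0))
        res = ci_concordance(prim, repl, level=0.95)
        assert res.n_variants == 152
        assert res.n_within_ci == 124
        assert res.percent_within_ci == 82

    def test_degenerate_narrow_ci_excludes(self):
        prim = [eff(vid="v", beta=0.5)]
        repl = [eff(vid="v", beta=0.0, se=1e-9)]
        assert ci_concordance(prim, repl).n_within_ci == 0

    def test_sign_consistency_counts(self):
        prim = [eff(vid="a", beta=0.5), eff(vid="b", beta=-0.5)]
        repl = [eff(vid="a", beta=0.1, se=1.0), eff(vid="b", beta=0.1, se=1.0)]
        assert ci_concordance(prim, repl).n_sign_consistent == 1

    def test_unmatched_variants_raise(self):
        with pytest.raises(ValueError, match="unmatched"):
            ci_concordance([eff(vid="a")], [eff(vid="b")])

    def test_alignment_applies_before_comparison(self):
        prim = [eff(vid="v", a1="A", a2="G", beta=0.5)]
        repl = [eff(vid="v", a1="G", a2="A", eaf=0.7, beta=-0.5, se=0.1)]
        res = ci_concordance(prim, repl)
        assert res.n_within_ci == 1
        assert res.n_sign_consistent == 1


class TestSeMonotonicity:
    def test_pooled_se_grows_with_heterogeneity(self):
        # larger between-study spread -> larger tau2 -> larger se*
        ses = []
        for spread in (0.0, 0.5, 1.0, 2.0):
            m = dl_meta(
                [eff(beta=0.1 + spread, se=0.1), eff(beta=0.1 - spread, se=0.1)]
            )
            ses.append(m.se)
        assert all(a <= b for a, b in zip(ses, ses[1:]))
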