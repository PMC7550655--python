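"""ANOVA (raw and from summaries), SNK post hoc, normality, Pearson."""

import numpy as np
import pytest
import scipy.stats as sps

from ivimr2.acquisition import ValidationError
from ivimr2.stats import (anova_from_summary, anova_oneway, ks_normality,
                          pearson, snk_posthoc)
from ivimr2.tumor import SummaryCell


class TestKsNormality:
    def test_accepts_large_normal_sample(self):
        x = np.random.default_rng(4).normal(size=500)
        res = ks_normality(x)
        assert 0.0 <= res.statistic <= 1.0
        assert res.p > 0.05
        assert not res.degenerate

    def test_rejects_two_point_mass(self):
        x = np.tile([0.0, 1.0], 50)
        res = ks_normality(x)
        assert res.p < 0.05

    def test_constant_sample_flagged_degenerate(self):
        res = ks_normality(np.full(10, 2.0))
        assert res.degenerate

    def test_minimum_sample_size(self):
        with pytest.raises(ValidationError):
            ks_normality([1.0, 2.0])


class TestAnovaOneway:
    def test_identical_group_means_give_near_zero_f(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 10)
        res = anova_oneway([base, base, base])
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res = anova_oneway([a, b])
        t = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t.statistic ** 2, abs=1e-10)
        assert res.p == pytest.approx(t.pvalue, abs=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.0, 2.0)]
        res = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.df_between == 3 and res.df_within == 28

    def test_zero_within_variance_flagged_infinite(self):
        res = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.F) and res.degenerate and res.p == 0.0

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 sits in its binomial band."""
        rng = np.random.default_rng(1)
        rej = sum(anova_oneway(rng.normal(0, 1, (4, 8))).p < 0.05
                  for _ in range(2000))
        assert 0.040 <= rej / 2000 <= 0.061

    def test_label_permutation_preserves_null_f_distribution(self):
        """Pooled-then-relabeled data give the same F distribution."""
        rng = np.random.default_rng(12)
        f_orig, f_perm = [], []
        for _ in range(400):
            data = rng.normal(0, 1, (4, 8))
            f_orig.append(anova_oneway(data).F)
            flat = data.ravel().copy()
            rng.shuffle(flat)
            f_perm.append(anova_oneway(flat.reshape(4, 8)).F)
        ks = sps.ks_2samp(f_orig, f_perm)
        assert ks.pvalue > 0.01


class TestAnovaFromSummary:
    def test_equals_raw_anova_on_computed_cells(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 8), (1, 10), (2, 6))]
        cells = [SummaryCell(float(g.mean()), float(g.std(ddof=1)), len(g))
                 for g in groups]
        raw = anova_oneway(groups)
        summ = anova_from_summary(cells)
        assert summ.F == pytest.approx(raw.F, rel=1e-12)
        assert summ.p == pytest.approx(raw.p, rel=1e-9)
        assert summ.ms_within == pytest.approx(raw.ms_within, rel=1e-12)

    def test_reference_volume_row(self):
        cells = [SummaryCell(m, s, 8) for m, s in
                 [(217.5, 60.1), (436.3, 59.6), (702.5, 42.9),
                  (1039.8, 93.9)]]
        res = anova_from_summary(cells)
        assert res.F == pytest.approx(225.693, rel=0.01)
        assert res.df_between == 3 and res.df_within == 28

    def test_zero_sd_unequal_means_flagged(self):
        cells = [SummaryCell(1.0, 0.0, 8), SummaryCell(2.0, 0.0, 8)]
        res = anova_from_summary(cells)
        assert np.isinf(res.F) and res.degenerate


class TestSnkPosthoc:
    def test_identical_groups_reject_nothing(self):
        groups = [np.full(8, 5.0) for _ in range(4)]
        assert snk_posthoc(groups).rejected == ()

    def test_two_groups_coincide_with_t_test(self):
        rng = np.random.default_rng(14)
        for shift in (0.0, 0.3, 0.8, 1.5, 3.0):
            a, b = rng.normal(0, 1, 8), rng.normal(shift, 1, 8)
            snk = snk_posthoc([a, b], labels=["a", "b"])
            t_reject = sps.ttest_ind(a, b).pvalue < 0.05
            assert (len(snk.rejected) == 1) == t_reject
            # q = t·sqrt(2) identity
            comp = snk.comparisons[0]
            assert comp.q == pytest.approx(
                abs(sps.ttest_ind(a, b).statistic) * np.sqrt(2), rel=1e-9)

    def test_extreme_separation_rejects_all_pairs(self):
        rng = np.random.default_rng(15)
        groups = [rng.normal(m, 1, 8) for m in (0, 10, 20, 30)]
        snk = snk_posthoc(groups)
        assert len(snk.rejected) == 6

    def test_rejections_closed_under_widening(self):
        """If an inner pair is rejected, every enclosing pair was
        tested and rejected too."""
        rng = np.random.default_rng(16)
        for _ in range(50):
            means = rng.uniform(0, 3, 4)
            groups = [rng.normal(m, 1, 8) for m in means]
            snk = snk_posthoc(groups, labels=list("abcd"))
            order = np.argsort([g.mean() for g in groups], kind="stable")
            labels_sorted = [list("abcd")[i] for i in order]
            pos = {lab: k for k, lab in enumerate(labels_sorted)}
            rejected = set(snk.rejected)
            for lo, hi in rejected:
                for lo2, hi2 in [(c.group_low, c.group_high)
                                 for c in snk.comparisons]:
                    if pos[lo2] <= pos[lo] and pos[hi2] >= pos[hi] \
                            and (lo2, hi2) != (lo, hi):
                        assert (lo2, hi2) in rejected

    def test_critical_values_match_studentized_range(self):
        rng = np.random.default_rng(17)
        groups = [rng.normal(m, 1, 8) for m in (0, 1, 2, 3)]
        snk = snk_posthoc(groups, alpha=0.05)
        df = 28
        for c in snk.comparisons:
            assert c.critical == pytest.approx(
                sps.studentized_range.ppf(0.95, c.r, df), rel=1e-9)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.n == 4
        assert res.strength == "moderate"

    @pytest.mark.parametrize("r_target,label", [
        (0.95, "high"), (0.65, "moderate"), (0.2, "weak")])
    def test_strength_labels(self, r_target, label):
        rng = np.random.default_rng(18)
        n = 4000
        x = rng.normal(size=n)
        y = r_target * x + np.sqrt(1 - r_target ** 2) * rng.normal(size=n)
        assert pearson(x, y).strength == label

    def test_affine_invariance_with_sign_flip(self):
        rng = np.random.default_rng(19)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = pearson(x, y).r
        assert pearson(3 * x + 5, y).r == pytest.approx(r0, rel=1e-12)
        assert pearson(x, -2 * y + 1).r == pytest.approx(-r0, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
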