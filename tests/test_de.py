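import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seqnoise import (
    bh_adjust,
    crt_ttest,
    glm_identity_gamma_test,
    glm_identity_poisson_test,
    run_de_table,
)


class TestPoissonGlm:
    def test_equal_means_give_null_statistic(self):
        r = glm_identity_poisson_test([10, 12, 8], [8, 12, 10])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_statistic(self):
        # means 100 vs 200, n=6 each: z = 100 / sqrt(100/6 + 200/6) = 100/sqrt(50)
        r = glm_identity_poisson_test([100] * 6, [200] * 6)
        assert r.statistic == pytest.approx(100 / np.sqrt(50), abs=1e-10)
        assert r.p_value == pytest.approx(2 * stats.norm.sf(100 / np.sqrt(50)), abs=1e-12)
        assert r.df is None  # normal reference

    def test_swapping_groups_flips_sign_keeps_p(self):
        y0, y1 = [5, 9, 7, 6, 8, 7], [12, 15, 13, 14, 11, 16]
        a = glm_identity_poisson_test(y0, y1)
        b = glm_identity_poisson_test(y1, y0)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_statistic_sign_tracks_mean_difference(self):
        r = glm_identity_poisson_test([10] * 3, [20, 21, 19])
        assert r.statistic > 0 and r.mean_g1 > r.mean_g0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            glm_identity_poisson_test([1.5, 2, 3], [1, 2, 3])

    def test_both_means_zero_is_na(self):
        with pytest.warns(UserWarning, match="zero"):
            r = glm_identity_poisson_test([0, 0], [0, 0])
        assert r.p_value is None and r.statistic is None


class TestGammaGlm:
    def test_identical_groups_null(self):
        y = [90.0, 100.0, 110.0]
        r = glm_identity_gamma_test(y, y)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_statistic_dispersion_df(self):
        y0 = [90.0, 100.0, 110.0, 95.0, 105.0, 100.0]
        y1 = [180.0, 200.0, 220.0, 190.0, 210.0, 200.0]
        r = glm_identity_gamma_test(y0, y1)
        assert r.dispersion == pytest.approx(0.005, abs=1e-12)
        assert r.statistic == pytest.approx(100 / np.sqrt(0.005 * 50000 / 6), abs=1e-8)
        assert r.statistic == pytest.approx(15.4919, abs=1e-4)
        assert r.df == 10

    def test_scale_invariance(self):
        y0 = np.array([3.0, 4.0, 5.0, 4.5])
        y1 = np.array([8.0, 9.0, 10.0, 9.5])
        a = glm_identity_gamma_test(y0, y1)
        b = glm_identity_gamma_test(17.3 * y0, 17.3 * y1)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_zero_value_error_mentions_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            glm_identity_gamma_test([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])

    def test_both_groups_constant_is_na(self):
        with pytest.warns(UserWarning, match="dispersion"):
            r = glm_identity_gamma_test([5.0, 5.0], [9.0, 9.0])
        assert r.p_value is None and r.dispersion == 0.0


class TestCrtTtest:
    def test_cube_root_is_applied(self):
        # groups whose cube roots are {1,2,3} vs {1,2,3}: exact null
        r = crt_ttest([1.0, 8.0, 27.0], [27.0, 1.0, 8.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_welch_matches_textbook_computation(self, rng):
        y0 = rng.gamma(5.0, 20.0, 6)
        y1 = rng.gamma(5.0, 80.0, 6)
        r = crt_ttest(y0, y1, variant="welch")
        x0, x1 = np.cbrt(y0), np.cbrt(y1)
        v0, v1 = x0.var(ddof=1) / 6, x1.var(ddof=1) / 6
        t = (x1.mean() - x0.mean()) / np.sqrt(v0 + v1)
        df = (v0 + v1) ** 2 / (v0**2 / 5 + v1**2 / 5)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-10)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-10)
        assert r.p_value < 0.05

    def test_pooled_variant_uses_n_minus_two_df(self):
        r = crt_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], variant="pooled")
        assert r.df == 4

    def test_zero_variance_both_groups_is_na(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r = crt_ttest([8.0] * 3, [8.0] * 3)
        assert r.p_value is None

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            crt_ttest([1, 2], [3, 4], variant="bayes")


class TestBhAdjust:
    def test_closed_form(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)


class TestRunDeTable:
    def test_cardinality(self, two_group_matrix):
        rows = run_de_table(two_group_matrix, methods=("poisson_glm", "crt_ttest"))
        assert len(rows) == 6  # 3 genes x 2 methods

    def test_requires_two_groups(self, two_group_matrix):
        m = two_group_matrix
        m1 = type(m)(m.data, {s: "A" for s in m.sample_ids})
        with pytest.raises(ValueError, match="2 groups"):
            run_de_table(m1)

    def test_pseudocount_applies_to_gamma_only(self, two_group_matrix):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = run_de_table(two_group_matrix, methods=("poisson_glm", "gamma_glm"),
                                pseudocount=0.5)
        by = {(r.method, r.gene_id): r for r in rows}
        g, p = by[("gamma_glm", "miR-1")], by[("poisson_glm", "miR-1")]
        assert g.mean_g0 == pytest.approx(p.mean_g0 + 0.5)
        assert p.mean_g0 == pytest.approx(4.0)

    def test_bh_adjustment_per_method(self, two_group_matrix):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = run_de_table(two_group_matrix, methods=("crt_ttest",), adjust="bh")
        defined = [r for r in rows if r.p_value is not None]
        raw = [r.p_value for r in defined]
        np.testing.assert_allclose([r.p_adjusted for r in defined], bh_adjust(raw))

    def test_invariant_to_sample_order_within_group(self, two_group_matrix, rng):
        m = two_group_matrix
        perm = ["a3", "a1", "a2", "b2", "b3", "b1"]
        m2 = type(m)(m.data[perm], dict(m.group_labels))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_de_table(m)
            b = run_de_table(m2)
        for ra, rb in zip(a, b):
            assert (ra.statistic is None) == (rb.statistic is None)
            if ra.statistic is not None:
                assert ra.statistic == pytest.approx(rb.statistic, rel=1e-12)


class TestIrlsOracle:
    """Closed-form Wald statistics agree with an iteratively reweighted GLM fit."""

    def test_matches_statsmodels_identity_link(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            n0, n1 = rng.integers(3, 9, size=2)
            X = sm.add_constant(np.r_[np.zeros(n0), np.ones(n1)])
            y0 = rng.poisson(rng.uniform(10, 200), n0).astype(float)
            y1 = rng.poisson(rng.uniform(10, 200), n1).astype(float)
            if y0.mean() == 0 or y1.mean() == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(np.r_[y0, y1], X,
                             family=sm.families.Poisson(sm.families.links.Identity())
                             ).fit(scale=1.0)
            r = glm_identity_poisson_test(y0, y1)
            assert r.statistic == pytest.approx(fit.params[1] / fit.bse[1], abs=1e-6)

            g0 = rng.gamma(8.0, rng.uniform(2, 40), n0)
            g1 = rng.gamma(8.0, rng.uniform(2, 40), n1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitg = sm.GLM(np.r_[g0, g1], X,
                              family=sm.families.Gamma(sm.families.links.Identity())
                              ).fit(scale="X2")
            rg = glm_identity_gamma_test(g0, g1)
            assert rg.statistic == pytest.approx(fitg.params[1] / fitg.bse[1], abs=1e-6)
            assert rg.dispersion == pytest.approx(fitg.scale, abs=1e-8)
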