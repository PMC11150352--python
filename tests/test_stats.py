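"""Statistical battery: oracles, identities and cross-checks."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cartimetrics import stats as st


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by brute force over all 2^n sign assignments."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    cdf = np.mean(w_all <= w_obs + 1e-9)
    sf = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))


def make_samples(rng, n=8, k=3):
    return st.PairedSamples(
        subjects=list(range(n)),
        conditions=[f"c{i}" for i in range(k)],
        values=rng.normal(50, 5, (n, k)),
    )


class TestRmAnova:
    def test_identical_columns(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = st.rm_anova(st.PairedSamples(list(range(5)), list("abc"), x))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_condition_f_equals_t_squared(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, (7, 2))
            s = st.PairedSamples(list(range(7)), list("ab"), x)
            f = st.rm_anova(s)
            t = st.paired_t(x[:, 0], x[:, 1])
            assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
            assert f.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_perfectly_additive_data_degenerates_to_infinite_f(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        res = st.rm_anova(st.PairedSamples(list(range(3)), list("ab"), x))
        t = np.inf  # paired differences have zero SD
        assert np.isinf(res.statistic) and res.statistic == t**2
        assert res.p_value == 0.0

    def test_subject_permutation_leaves_f_unchanged(self, rng):
        x = rng.normal(0, 1, (6, 3))
        s1 = st.PairedSamples(list(range(6)), list("abc"), x)
        s2 = st.PairedSamples(list(range(6)), list("abc"), x[::-1])
        assert st.rm_anova(s1).statistic == pytest.approx(
            st.rm_anova(s2).statistic, rel=1e-12
        )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(50, 5, (10, 3))
        res = st.rm_anova(st.PairedSamples(list(range(10)), list("abc"), x))
        df = pd.DataFrame(x, columns=list("abc")).reset_index().melt(id_vars="index")
        aov = pg.rm_anova(data=df, dv="value", within="variable", subject="index")
        assert res.statistic == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            st.PairedSamples([1, 2], list("ab"), np.zeros((2, 2)))  # n < 3
        with pytest.raises(ValueError):
            st.PairedSamples([1, 2, 3], ["a"], np.zeros((3, 1)))  # k < 2


class TestTukeyKramer:
    def test_identical_columns_all_p_one(self):
        x = np.tile(np.arange(4.0)[:, None], (1, 3))
        res = st.tukey_kramer(st.PairedSamples(list(range(4)), list("abc"), x))
        assert all(p == 1.0 for p in res.adjusted_p.values())

    def test_two_conditions_equal_paired_t(self, rng):
        """With k = 2 the studentized range collapses to q = t * sqrt(2)."""
        x = rng.normal(10, 2, (9, 2))
        s = st.PairedSamples(list(range(9)), list("ab"), x)
        tk = st.tukey_kramer(s)
        t = st.paired_t(x[:, 0], x[:, 1])
        assert list(tk.adjusted_p.values())[0] == pytest.approx(t.p_value, rel=1e-6)

    def test_adjusted_p_never_below_unadjusted(self, rng):
        for _ in range(5):
            s = make_samples(rng, n=6, k=4)
            res = st.tukey_kramer(s)
            for pair in res.adjusted_p:
                assert res.adjusted_p[pair] >= res.unadjusted_p[pair] - 1e-12


class TestWilcoxon:
    def test_n5_all_positive(self):
        res = st.wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(2 / 32)

    def test_degenerate_all_zero(self):
        res = st.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_exact_matches_enumeration(self, n, rng):
        for _ in range(3):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            mine = st.wilcoxon_signed_rank(x, y, mode="exact").p_value
            assert mine == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self, rng):
        x = np.array([3.0, 4.0, 5.0, 7.0, 1.0, 2.0, 9.0, 3.5])
        y = np.array([1.0, 2.0, 3.0, 5.0, 3.0, 4.0, 7.0, 1.5])  # tied |d| = 2
        mine = st.wilcoxon_signed_rank(x, y, mode="exact").p_value
        assert mine == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.3, 1, 10)
        mine = st.wilcoxon_signed_rank(x, y, mode="exact").p_value
        ref = sps.wilcoxon(x, y, mode="exact").pvalue
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_approx_mode_reasonable(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)
        mine = st.wilcoxon_signed_rank(x, y, mode="approx").p_value
        ref = sps.wilcoxon(x, y, correction=False, mode="approx").pvalue
        assert mine == pytest.approx(ref, rel=1e-6)


class TestPairedT:
    def test_closed_form_example(self):
        res = st.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)

    def test_zero_mean_difference(self):
        res = st.paired_t([1.0, -1.0, 2.0, -2.0], [0.0, 0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_sign_flip_symmetry(self, rng):
        x = rng.normal(1, 1, 12)
        y = rng.normal(0, 1, 12)
        a = st.paired_t(x, y)
        b = st.paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.normal(1, 1, 15)
        y = rng.normal(0, 1, 15)
        res = st.paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


class TestCohensD:
    def test_simple_value(self):
        assert st.cohens_d_paired([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]) == pytest.approx(2.0)

    def test_identical_vectors_zero(self):
        assert st.cohens_d_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_scale_invariance(self, rng):
        x = rng.normal(1, 1, 10)
        y = rng.normal(0, 1, 10)
        assert st.cohens_d_paired(7 * x, 7 * y) == pytest.approx(
            st.cohens_d_paired(x, y), rel=1e-12
        )


class TestMinSampleSize:
    def test_study_power_analysis_inputs(self):
        """Power 80%, alpha 0.01 two-sided, d = 1.24 gives n = 8 by the
        z-formula: ceil(((2.5758 + 0.8416) / 1.24)^2) = 8."""
        assert st.min_sample_size(0.80, 0.01, 1.24) == 8

    def test_z_formula_arithmetic(self):
        # ceil((1.95996 + 0.84162)^2) = ceil(7.849) = 8
        assert st.min_sample_size(0.80, 0.05, 1.0) == 8

    def test_monotone_decreasing_in_effect_size(self):
        ns = [st.min_sample_size(0.80, 0.01, d) for d in (0.3, 0.6, 1.24, 3.0, 30.0)]
        assert ns == sorted(ns, reverse=True)
        assert ns[-1] == 1

    def test_monotone_nonincreasing_in_alpha(self):
        ns = [st.min_sample_size(0.80, a, 1.0) for a in (0.001, 0.01, 0.05, 0.2)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_noncentral_t_mode_is_larger(self):
        assert st.min_sample_size(0.80, 0.01, 1.24, method="nct") >= 8

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            st.min_sample_size(1.5, 0.01, 1.0)
        with pytest.raises(ValueError):
            st.min_sample_size(0.8, 0.01, -1.0)


class TestTypeIErrorCalibration:
    def test_null_rejection_rates_at_alpha_001(self):
        """Under the null, paired-t and exact Wilcoxon reject at most
        alpha + 2 Monte-Carlo SEs (10^4 seeded replicates, n = 10)."""
        alpha = 0.01
        reps = 10**4
        rng = np.random.default_rng(2024)
        data = rng.normal(0, 1, (reps, 10))
        zero = np.zeros(10)
        # vectorized paired t
        t = data.mean(axis=1) / (data.std(axis=1, ddof=1) / np.sqrt(10))
        p_t = 2 * sps.t.sf(np.abs(t), 9)
        rate_t = np.mean(p_t <= alpha)
        rate_w = np.mean([
            st.wilcoxon_signed_rank(row, zero, mode="exact").p_value <= alpha
            for row in data
        ])
        bound = alpha + 2 * np.sqrt(alpha * (1 - alpha) / reps)
        assert rate_t <= bound
        assert rate_w <= bound
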