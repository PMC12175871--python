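import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from prhismkit import agreement as ag


def table_from_counts(counts, categories=None):
    counts = np.asarray(counts, dtype=float)
    cats = tuple(categories or range(counts.shape[0]))
    return ag.ContingencyTable(cats, counts, int(counts.sum()))


def vectors_from_counts(counts):
    """Reconstruct rating vectors whose cross-tabulation is ``counts``."""
    x, y = [], []
    counts = np.asarray(counts, dtype=int)
    for (i, j), c in np.ndenumerate(counts):
        x.extend([i] * c)
        y.extend([j] * c)
    return np.array(x), np.array(y)


class TestBuildTable:
    def test_identity_diagonal(self):
        t = ag.build_table([1, 2], [1, 2], [1, 2])
        assert np.array_equal(t.counts, np.eye(2))
        assert t.n == 2

    def test_full_enumeration(self):
        t = ag.build_table([1, 1, 2, 2], [1, 2, 1, 2], [1, 2])
        assert np.array_equal(t.counts, np.ones((2, 2)))

    def test_na_dropped_pairwise(self):
        t = ag.build_table([1, None], [1, 2], [1, 2])
        assert t.n == 1
        assert t.counts[0, 0] == 1

    def test_all_na_errors(self):
        with pytest.raises(ValueError, match="no subjects"):
            ag.build_table([None, None], [1, 2], [1, 2])

    def test_unknown_value_errors(self):
        with pytest.raises(ValueError, match="not in declared categories"):
            ag.build_table([1, 3], [1, 2], [1, 2])


class TestWeightedKappa:
    def test_perfect_agreement(self):
        t = ag.build_table([0, 1, 2, 1], [0, 1, 2, 1], range(3))
        for scheme in ag.WeightScheme:
            assert ag.weighted_kappa(t, scheme).kappa == pytest.approx(1.0)

    def test_identity_hand_example(self):
        # p_o = 5/6, p_e = 1/2 -> kappa = 2/3
        t = ag.build_table([1, 1, 1, 2, 2, 2], [1, 1, 2, 2, 2, 2], [1, 2])
        est = ag.weighted_kappa(t, "identity")
        assert est.p_o == pytest.approx(5 / 6)
        assert est.p_e == pytest.approx(1 / 2)
        assert est.kappa == pytest.approx(2 / 3)

    def test_quadratic_hand_example(self):
        # p_o = 0.875, p_e = 0.59375 -> kappa = 0.692307...
        t = ag.build_table([0, 1, 2, 0], [0, 2, 2, 1], range(3))
        est = ag.weighted_kappa(t, "quadratic")
        assert est.p_o == pytest.approx(0.875)
        assert est.p_e == pytest.approx(0.59375)
        assert est.kappa == pytest.approx(0.6923, abs=5e-5)

    def test_degenerate_table_errors(self):
        counts = np.zeros((2, 2))
        counts[0, 0] = 4
        with pytest.raises(ag.DegenerateTableError):
            ag.weighted_kappa(table_from_counts(counts), "identity")

    @pytest.mark.parametrize("scheme", list(ag.WeightScheme))
    def test_matches_sklearn_on_random_tables(self, scheme, rng):
        weights = {"identity": None, "linear": "linear",
                   "quadratic": "quadratic"}[scheme.value]
        for _ in range(50):
            k = rng.integers(2, 6)
            x = rng.integers(0, k, size=40)
            y = np.where(rng.random(40) < 0.5, x, rng.integers(0, k, size=40))
            t = ag.build_table(x, y, range(k))
            mine = ag.weighted_kappa(t, scheme).kappa
            ref = cohen_kappa_score(x, y, labels=list(range(k)),
                                    weights=weights)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_transpose_symmetry(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 5, size=(4, 4))
            if counts.sum() == 0:
                continue
            t = table_from_counts(counts)
            for scheme in ag.WeightScheme:
                try:
                    a = ag.weighted_kappa(t, scheme).kappa
                    b = ag.weighted_kappa(t.transpose(), scheme).kappa
                except ag.DegenerateTableError:
                    continue
                assert a == pytest.approx(b, abs=1e-12)

    def test_kappa_bounded_by_observed_agreement(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 6, size=(3, 3))
            if counts.sum() < 2:
                continue
            try:
                est = ag.weighted_kappa(table_from_counts(counts), "identity")
            except ag.DegenerateTableError:
                continue
            assert est.kappa <= est.p_o + 1e-12

    def test_kappa_one_iff_diagonal(self, rng):
        diag = table_from_counts(np.diag([3, 2, 1]))
        assert ag.weighted_kappa(diag, "identity").kappa == pytest.approx(1.0)
        off = np.diag([3.0, 2, 1])
        off[0, 1] = 1
        est = ag.weighted_kappa(table_from_counts(off), "identity")
        assert est.kappa < 1.0


class TestWeightMatrix:
    @pytest.mark.parametrize("scheme", list(ag.WeightScheme))
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_properties(self, scheme, k):
        w = ag.weight_matrix(k, scheme)
        assert np.allclose(np.diag(w), 1.0)
        assert np.allclose(w, w.T)
        assert (w >= 0).all() and (w <= 1).all()

    def test_known_values(self):
        w = ag.weight_matrix(5, "quadratic")
        assert w[0, 4] == pytest.approx(0.0)
        assert w[0, 1] == pytest.approx(1 - 1 / 16)
        wl = ag.weight_matrix(5, "linear")
        assert wl[0, 2] == pytest.approx(0.5)


class TestKappaSe:
    def test_replication_scaling(self):
        counts = np.array([[5, 2, 0], [1, 6, 2], [0, 1, 3]], dtype=float)
        se1 = ag.kappa_se(table_from_counts(counts), "quadratic")
        se9 = ag.kappa_se(table_from_counts(counts * 9), "quadratic")
        assert se9 == pytest.approx(se1 / 3, rel=1e-9)

    def test_all_diagonal_has_zero_se(self):
        t = table_from_counts(np.diag([4, 3, 2]))
        assert ag.kappa_se(t, "identity") == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("scheme", ["identity", "quadratic"])
    def test_against_bootstrap_oracle(self, scheme):
        counts = np.array([[12, 3, 1], [2, 15, 4], [1, 3, 9]], dtype=float)
        t = table_from_counts(counts)
        asym = ag.kappa_se(t, scheme)
        boot = ag.bootstrap_kappa_se(t, scheme, n_boot=10_000, seed=99)
        assert asym == pytest.approx(boot, rel=0.15)


class TestKappaCi:
    def test_zero_se_degenerate(self):
        assert ag.kappa_ci(0.4, 0.0, 0.95) == (0.4, 0.4)

    def test_95_percent_interval(self):
        lo, hi = ag.kappa_ci(0.5, 0.1, 0.95)
        assert lo == pytest.approx(0.304, abs=5e-4)
        assert hi == pytest.approx(0.696, abs=5e-4)

    def test_90_percent_uses_z_1p645(self):
        lo, hi = ag.kappa_ci(0.0, 1.0, 0.90)
        assert hi == pytest.approx(stats.norm.ppf(0.95), abs=1e-9)
        assert hi == pytest.approx(1.6449, abs=1e-4)

    def test_not_truncated_but_flagged(self):
        with pytest.warns(UserWarning, match="outside"):
            lo, hi = ag.kappa_ci(0.9, 0.2, 0.95)
        assert hi > 1.0


class TestPairwiseMeanKappa:
    def test_identical_raters(self):
        m = np.tile(np.array([0, 1, 2, 3, 4, 2])[:, None], (1, 4))
        pa = ag.pairwise_mean_kappa(m, "quadratic", level=0.90,
                                    categories=range(5))
        assert pa.n_pairs == 6
        assert pa.mean_kappa == pytest.approx(1.0)
        assert pa.ci_low == pytest.approx(1.0) and pa.ci_high == pytest.approx(1.0)

    def test_two_raters_reduces_to_single_kappa(self, rng):
        x = rng.integers(0, 4, 20)
        y = rng.integers(0, 4, 20)
        pa = ag.pairwise_mean_kappa(np.column_stack([x, y]), "quadratic",
                                    categories=range(4))
        single = ag.weighted_kappa(ag.build_table(x, y, range(4)), "quadratic")
        assert pa.mean_kappa == pytest.approx(single.kappa)

    def test_three_raters_equals_mean_of_pair_kappas(self, rng):
        m = rng.integers(0, 3, size=(8, 3))
        pa = ag.pairwise_mean_kappa(m, "linear", categories=range(3))
        expected = np.mean([
            cohen_kappa_score(m[:, a], m[:, b], labels=[0, 1, 2],
                              weights="linear")
            for a, b in itertools.combinations(range(3), 2)])
        assert pa.mean_kappa == pytest.approx(expected, abs=1e-12)

    def test_fast_jackknife_matches_explicit_loop(self, rng):
        m = rng.integers(0, 5, size=(25, 4))
        pa = ag.pairwise_mean_kappa(m, "quadratic", categories=range(5))
        loo = []
        pairs = list(itertools.combinations(range(4), 2))
        for i in range(25):
            sub = np.delete(m, i, axis=0)
            loo.append(np.mean([
                cohen_kappa_score(sub[:, a], sub[:, b],
                                  labels=list(range(5)), weights="quadratic")
                for a, b in pairs]))
        loo = np.asarray(loo)
        se = np.sqrt(24 / 25 * ((loo - loo.mean()) ** 2).sum())
        assert pa.se == pytest.approx(se, abs=1e-10)

    def test_na_handled_pairwise(self):
        m = np.array([[0, 0, None], [1, 1, 1], [2, 2, 2], [3, 3, 3],
                      [4, 4, 4], [0, 1, 0]], dtype=object)
        pa = ag.pairwise_mean_kappa(m, "identity", categories=range(5))
        # pair (0,1) keeps all 6 subjects; pairs with rater 2 keep 5
        ns = {lab: est.n for lab, est in zip(pa.pair_labels, pa.pair_estimates)}
        assert ns["r1-r2"] == 6
        assert ns["r1-r3"] == 5 and ns["r2-r3"] == 5

    def test_degenerate_pair_excluded_with_warning(self):
        m = np.array([[1, 1, 1], [1, 1, 2], [1, 1, 1], [1, 1, 2]],
                     dtype=object)
        with pytest.warns(UserWarning, match="excluded"):
            pa = ag.pairwise_mean_kappa(m, "identity", categories=[1, 2])
        assert pa.n_pairs == 2
        assert len(pa.excluded_pairs) == 1


class TestKappaZTest:
    def test_null_value(self):
        res = ag.kappa_z_test(0.5, 0.5, 0.1)
        assert res.z == 0.0 and res.p_value == 1.0 and not res.reject

    def test_hand_example(self):
        res = ag.kappa_z_test(0.61, 0.53, 0.04, alpha=0.10)
        assert res.z == pytest.approx(2.0)
        assert res.p_value == pytest.approx(0.0455, abs=5e-4)
        assert res.reject

    def test_zero_se_requires_equality(self):
        with pytest.raises(ValueError):
            ag.kappa_z_test(0.6, 0.5, 0.0)
        assert not ag.kappa_z_test(0.5, 0.5, 0.0).reject


class TestIcc:
    def test_identical_columns(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 3))
        est = ag.icc(m)
        assert est.icc == pytest.approx(1.0)

    def test_variance_ratio_half(self, rng):
        # subject and error variances 1:1 -> true ICC(A,1) = 0.5; the
        # Monte-Carlo SD of the estimate at 500 subjects is ~0.02
        subj = rng.normal(0, 1, size=(500, 1))
        m = subj + rng.normal(0, 1, size=(500, 4))
        est = ag.icc(m)
        assert est.icc == pytest.approx(0.5, abs=0.07)

    def test_hand_anova(self):
        # 4 subjects x 3 raters worked through the two-way mean squares
        m = np.array([[9., 2., 5.], [6., 1., 3.], [8., 4., 6.], [7., 1., 2.]])
        n, k = m.shape
        grand = m.mean()
        msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((m - m.mean(1, keepdims=True) - m.mean(0) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert ag.icc(m).icc == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        m = rng.normal(0, 1, (15, 1)) + rng.normal(0, 0.8, (15, 4))
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(15), 4),
            "rater": np.tile(np.arange(4), 15),
            "score": m.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subj", raters="rater",
                                 ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        est = ag.icc(m)
        assert est.icc == pytest.approx(row["ICC"], abs=1e-9)

    def test_listwise_deletion(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 4.0], [3.0, 3.0]])
        est = ag.icc(m)
        assert est.n_subjects == 3

    def test_no_between_subject_variance(self):
        m = np.ones((5, 3))
        m += np.arange(3)[None, :] * 0.1  # rater effects only
        with pytest.warns(UserWarning, match="0 boundary"):
            est = ag.icc(m)
        assert est.icc == 0.0


class TestInterpretation:
    @pytest.mark.parametrize("kappa, label", [
        (0.52, "moderate"),
        (0.63, "substantial"),
        (-0.05, "no agreement"),
        (0.10, "slight"),
        (0.35, "fair"),
        (0.90, "almost perfect"),
        (1.0, "almost perfect"),
        (0.61, "substantial"),
        (0.60, "moderate"),
    ])
    def test_bands(self, kappa, label):
        assert ag.interpret_kappa(kappa) == label

    def test_sufficient_threshold(self):
        assert ag.is_sufficient_agreement(0.61)
        assert not ag.is_sufficient_agreement(0.609)


class TestCrossInstrumentKappa:
    def test_identical_after_alignment(self):
        prhism = [0, 1, 2, 3, 4, 2, 1]
        discern = [1, 2, 3, 4, 5, 3, 2]   # same judgments on the 1-5 scale
        est = ag.cross_instrument_kappa(prhism, discern, range(5),
                                        range(1, 6), "quadratic")
        assert est.kappa == pytest.approx(1.0)

    def test_equals_union_support_table(self):
        classification = [1, 2, 3, 4, 2, 1, 3]      # 4-band codes
        expert = [1, 3, 4, 5, 2, 2, 3]              # 1-5 judgments
        est = ag.cross_instrument_kappa(classification, expert,
                                        range(1, 5), range(1, 6), "quadratic")
        shifted_a = [v - 1 for v in classification]
        shifted_b = [v - 1 for v in expert]
        direct = ag.weighted_kappa(
            ag.build_table(shifted_a, shifted_b, range(5)), "quadratic")
        assert est.kappa == pytest.approx(direct.kappa)
        assert est.p_e == pytest.approx(direct.p_e)

    def test_non_consecutive_scale_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            ag.cross_instrument_kappa([1], [1], [1, 3, 5], [1, 2, 3])


class TestBruteForceEquivalence:
    def test_exhaustive_2x2_tables(self):
        """Identity-weight kappa equals the textbook computation on every
        2x2 table with n <= 6 (degenerate marginals excluded)."""
        checked = 0
        for a, b, c, d in itertools.product(range(7), repeat=4):
            n = a + b + c + d
            if n == 0 or n > 6:
                continue
            counts = np.array([[a, b], [c, d]], dtype=float)
            x, y = vectors_from_counts(counts)
            # brute force from first principles
            p_o = (a + d) / n
            p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n ** 2
            t = table_from_counts(counts)
            if p_e >= 1 - 1e-12:
                with pytest.raises(ag.DegenerateTableError):
                    ag.weighted_kappa(t, "identity")
                continue
            mine = ag.weighted_kappa(t, "identity").kappa
            assert mine == pytest.approx((p_o - p_e) / (1 - p_e), abs=1e-12)
            assert mine == pytest.approx(
                cohen_kappa_score(x, y, labels=[0, 1]), abs=1e-12)
            checked += 1
        assert checked > 100
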