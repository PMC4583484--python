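"""Unit and property tests for the generalized CMH statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import chi2_contingency, hypergeom, pearsonr

from stepcmh import (
    CMHResult,
    ContingencyTable3D,
    ScoreScheme,
    cmh_test,
    expected_counts,
    make_score_matrix,
    variance_matrix,
)
from stepcmh.exceptions import (
    DegenerateStratumError,
    EmptyStratumError,
    UntestableError,
    ValidationError,
)

from conftest import random_table


class TestScoreMatrix:
    @pytest.mark.parametrize(
        "n_levels, scheme, expected",
        [
            (3, ScoreScheme.nominal(), [[1, 0, -1], [0, 1, -1]]),
            (2, ScoreScheme.nominal(), [[1, -1]]),
            (3, ScoreScheme.ordinal((0, 1, 2)), [[0, 1, 2]]),
            (4, ScoreScheme.ordinal((1, 2, 3, 4)), [[1, 2, 3, 4]]),
        ],
    )
    def test_examples(self, n_levels, scheme, expected):
        np.testing.assert_array_equal(
            make_score_matrix(n_levels, scheme), np.array(expected, float)
        )

    def test_invalid_levels(self):
        with pytest.raises(ValidationError):
            make_score_matrix(1, ScoreScheme.nominal())

    def test_score_length_mismatch(self):
        with pytest.raises(ValidationError):
            make_score_matrix(4, ScoreScheme.ordinal((0, 1, 2)))

    def test_decreasing_scores_rejected(self):
        with pytest.raises(ValidationError):
            ScoreScheme.ordinal((2, 1, 0))

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError):
            ScoreScheme.ordinal((1, 1, 1))

    def test_genetic_model_codings(self):
        assert ScoreScheme.genetic_model("dominant").scores == (0.0, 1.0, 1.0)
        assert ScoreScheme.genetic_model("recessive").scores == (0.0, 0.0, 1.0)
        assert ScoreScheme.genetic_model("codominant").kind == "nominal"


class TestExpectedCounts:
    def test_symmetric_margins(self):
        np.testing.assert_allclose(
            expected_counts(np.array([[1, 0], [0, 1]])), [0.5, 0.5, 0.5, 0.5]
        )

    def test_uniform_table_is_exactly_independent(self):
        slc = np.full((3, 4), 5)
        np.testing.assert_allclose(expected_counts(slc), slc.ravel())

    def test_matches_product_of_margins_oracle(self, rng):
        for _ in range(20):
            slc = random_table(rng, shape=(2, 3), high=6)
            mu = expected_counts(slc)
            n = slc.sum()
            for i in range(2):
                for j in range(3):
                    assert mu[i * 3 + j] == pytest.approx(
                        slc[i].sum() * slc[:, j].sum() / n
                    )
            assert mu.sum() == pytest.approx(n)

    def test_empty_stratum(self):
        with pytest.raises(EmptyStratumError):
            expected_counts(np.zeros((2, 2)))


def _enumerated_covariance(row_margins, col_margins):
    """Probability-weighted covariance of 2x2 cell counts with fixed margins."""
    n = sum(row_margins)
    r1, _ = row_margins
    c1, _ = col_margins
    tables, probs = [], []
    for n11 in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        t = np.array([[n11, r1 - n11], [c1 - n11, n - r1 - c1 + n11]])
        tables.append(t.ravel())
        probs.append(hypergeom.pmf(n11, n, c1, r1))
    tables = np.array(tables, float)
    probs = np.array(probs)
    mean = probs @ tables
    centred = tables - mean
    return (centred.T * probs) @ centred


class TestVarianceMatrix:
    def test_diagonal_formula(self, rng):
        slc = random_table(rng, shape=(2, 2))
        n = slc.sum()
        r1, c1 = slc[0].sum(), slc[:, 0].sum()
        v = variance_matrix(slc)
        expect = r1 * (n - r1) * c1 * (n - c1) / (n**2 * (n - 1))
        assert v[0, 0] == pytest.approx(expect)

    def test_zero_row_margin_gives_zero_matrix(self):
        v = variance_matrix(np.array([[0, 0], [2, 3]]))
        np.testing.assert_allclose(v, 0.0)

    @pytest.mark.parametrize(
        "row_margins, col_margins", [((1, 2), (1, 2)), ((2, 1), (2, 1)),
                                     ((3, 2), (1, 4))]
    )
    def test_matches_hypergeometric_enumeration(self, row_margins, col_margins):
        # Any 2x2 realization with these margins has the same variance matrix.
        n = sum(row_margins)
        r1, c1 = row_margins[0], col_margins[0]
        n11 = max(0, r1 + c1 - n)
        slc = np.array([[n11, r1 - n11], [c1 - n11, n - r1 - c1 + n11]])
        np.testing.assert_allclose(
            variance_matrix(slc),
            _enumerated_covariance(row_margins, col_margins),
            atol=1e-12,
        )

    def test_symmetry_and_nonnegative_diagonal(self, rng):
        slc = random_table(rng, shape=(3, 3))
        v = variance_matrix(slc)
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert (np.diag(v) >= -1e-12).all()
        # margins fixed: rows sum to zero over all cells
        np.testing.assert_allclose(v.sum(axis=1), 0.0, atol=1e-9)

    def test_degenerate_stratum(self):
        with pytest.raises(DegenerateStratumError):
            variance_matrix(np.array([[1, 0], [0, 0]]))


class TestCMHTest:
    def test_general_df_binary_trait_three_genotypes(self, rng):
        res = cmh_test(ContingencyTable3D(random_table(rng, (2, 3))))
        assert res.test_type == "general"
        assert res.df == 2

    def test_mean_score_df(self, rng):
        res = cmh_test(
            ContingencyTable3D(random_table(rng, (3, 3))),
            ScoreScheme.nominal(),
            ScoreScheme.ordinal((0, 1, 2)),
        )
        assert res.test_type == "mean_score"
        assert res.df == 2  # (I-1) with nominal rows on I=3

    def test_correlation_df_is_one(self, rng):
        res = cmh_test(
            ContingencyTable3D(random_table(rng, (3, 3))),
            ScoreScheme.ordinal((1, 2, 3)),
            ScoreScheme.ordinal((0, 1, 2)),
        )
        assert res.test_type == "correlation"
        assert res.df == 1

    def test_proportional_rows_give_zero_statistic(self):
        t = np.array([[2, 4, 6], [1, 2, 3]])
        res = cmh_test(ContingencyTable3D(t))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_k1_general_equals_scaled_pearson(self, rng):
        for _ in range(25):
            t = random_table(rng, (2, 3))
            n = t.sum()
            pearson = chi2_contingency(t, correction=False).statistic
            res = cmh_test(ContingencyTable3D(t))
            assert res.statistic == pytest.approx((n - 1) / n * pearson,
                                                  abs=1e-10)

    def test_k1_correlation_equals_nminus1_rsquared(self, rng):
        for _ in range(10):
            t = random_table(rng, (3, 3))
            n = t.sum()
            xs, ys = [], []
            for i in range(3):
                for j in range(3):
                    xs += [i] * t[i, j]
                    ys += [j] * t[i, j]
            r = pearsonr(xs, ys).statistic
            res = cmh_test(
                ContingencyTable3D(t),
                ScoreScheme.ordinal((0, 1, 2)),
                ScoreScheme.ordinal((0, 1, 2)),
            )
            assert res.statistic == pytest.approx((n - 1) * r**2, abs=1e-10)

    def test_2x2xk_equals_classical_mantel_haenszel(self, rng):
        for _ in range(10):
            tab = np.stack(
                [random_table(rng, (2, 2), low=1) for _ in range(4)], axis=2
            )
            num = den = 0.0
            for k in range(4):
                s = tab[:, :, k].astype(float)
                nk = s.sum()
                num += s[0, 0] - s[0].sum() * s[:, 0].sum() / nk
                den += (
                    s[0].sum() * s[1].sum() * s[:, 0].sum() * s[:, 1].sum()
                    / (nk**2 * (nk - 1))
                )
            res = cmh_test(ContingencyTable3D(tab))
            assert res.df == 1
            assert res.statistic == pytest.approx(num**2 / den, abs=1e-10)

    def test_invariant_under_stratum_permutation(self, rng):
        tab = np.stack([random_table(rng, (2, 3)) for _ in range(5)], axis=2)
        base = cmh_test(ContingencyTable3D(tab))
        perm = cmh_test(ContingencyTable3D(tab[:, :, rng.permutation(5)]))
        assert perm.statistic == pytest.approx(base.statistic, abs=1e-10)
        assert perm.df == base.df

    def test_general_invariant_under_level_relabeling(self, rng):
        tab = np.stack([random_table(rng, (3, 3)) for _ in range(3)], axis=2)
        base = cmh_test(ContingencyTable3D(tab))
        pi, pj = rng.permutation(3), rng.permutation(3)
        shuffled = cmh_test(ContingencyTable3D(tab[np.ix_(pi, pj)]))
        assert shuffled.statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_correlation_invariant_under_affine_scores(self, rng):
        tab = np.stack([random_table(rng, (3, 3)) for _ in range(3)], axis=2)
        base = cmh_test(
            ContingencyTable3D(tab),
            ScoreScheme.ordinal((0, 1, 2)),
            ScoreScheme.ordinal((0, 1, 2)),
        )
        scaled = cmh_test(
            ContingencyTable3D(tab),
            ScoreScheme.ordinal((5, 7, 9)),     # 2u + 5
            ScoreScheme.ordinal((-1, 2, 5)),    # 3v - 1
        )
        assert scaled.statistic == pytest.approx(base.statistic, abs=1e-10)

    def test_all_zero_stratum_is_inert(self, rng):
        tab = np.stack([random_table(rng, (2, 3)) for _ in range(3)], axis=2)
        padded = np.concatenate([tab, np.zeros((2, 3, 1), int)], axis=2)
        base = cmh_test(ContingencyTable3D(tab))
        res = cmh_test(ContingencyTable3D(padded))
        assert res.statistic == pytest.approx(base.statistic, abs=1e-12)
        assert res.df == base.df
        assert res.p_value == pytest.approx(base.p_value, abs=1e-12)
        assert res.n_strata_dropped == 1

    def test_statistic_and_pvalue_ranges(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 4))
            shape = (int(rng.integers(2, 4)), int(rng.integers(2, 4)))
            tab = np.stack(
                [rng.integers(0, 7, size=shape) for _ in range(k)], axis=2
            )
            if tab.sum() < 2:
                continue
            try:
                res = cmh_test(ContingencyTable3D(tab))
            except UntestableError:
                continue
            assert res.statistic >= 0.0
            assert 0.0 <= res.p_value <= 1.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        hnp.arrays(np.int64, st.tuples(st.integers(2, 3), st.integers(2, 4),
                                       st.integers(1, 4)),
                   elements=st.integers(0, 6))
    )
    def test_statistic_nonnegative_pvalue_in_unit_interval(self, counts):
        if counts.sum() < 1:
            return
        try:
            res = cmh_test(ContingencyTable3D(counts))
        except UntestableError:
            return
        assert res.statistic >= 0.0
        assert 0.0 <= res.p_value <= 1.0
        assert res.df >= 0

    def test_rank_deficiency_with_empty_genotype_column(self, rng):
        t = random_table(rng, (2, 2))
        tab = np.concatenate([t, np.zeros((2, 1), int)], axis=1)
        res = cmh_test(ContingencyTable3D(tab))
        assert res.rank_deficient
        assert res.df == 1  # only 2 observed genotype columns

    def test_all_strata_degenerate(self):
        tab = np.zeros((2, 3, 2), int)
        tab[0, 0, 0] = 1
        with pytest.raises(UntestableError):
            cmh_test(ContingencyTable3D(tab))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable3D(np.array([[[1], [-1]], [[2], [3]]]))

    def test_nonfinite_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable3D(np.array([[[1.0], [np.nan]], [[2.0], [3.0]]]))
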