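"""The seven association measures: worked values, algebraic identities and
symmetries, with scikit-learn / scipy as independent oracles."""

import math

import numpy as np
import pytest

from esfuse import (
    ContingencyTable,
    cohens_w,
    compute_all,
    cramers_v,
    gk_lambda,
    gk_tau,
    pearsons_c,
    tschuprows_t,
    uncertainty_coefficient,
)
from esfuse.measures import pearsons_c_from_w, tschuprows_t_from_w

INDEPENDENT = ContingencyTable([[10, 10, 10], [10, 10, 10]])
PERFECT = ContingencyTable([[10, 0], [0, 10]])
WORKED = ContingencyTable([[10, 20], [30, 40]])  # chi2 = 0.7937


class TestWorkedValues:
    @pytest.mark.parametrize(
        "measure",
        [cramers_v, tschuprows_t, pearsons_c, cohens_w, gk_tau,
         uncertainty_coefficient, gk_lambda],
    )
    def test_zero_under_independence(self, measure):
        assert measure(INDEPENDENT) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "measure,expected",
        [
            (cramers_v, 1.0),
            (tschuprows_t, 1.0),
            (pearsons_c, math.sqrt(0.5)),
            (cohens_w, 1.0),
            (gk_tau, 1.0),
            (uncertainty_coefficient, 1.0),
            (gk_lambda, 1.0),
        ],
    )
    def test_perfect_2x2_association(self, measure, expected):
        assert measure(PERFECT) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "measure,expected",
        [
            (cramers_v, 0.0891),  # sqrt(0.7937 / 100)
            (gk_tau, 0.0079365),  # direct formula evaluation
            (uncertainty_coefficient, 0.006584),  # H(X)=0.610864, H(X|Y)=0.606842 nats
            (gk_lambda, 0.0),  # same modal row in every column: E1 = E2 = 30
        ],
    )
    def test_hand_worked_2x2(self, measure, expected):
        assert measure(WORKED) == pytest.approx(expected, abs=1e-4)

    def test_lambda_modal_shift(self):
        # E1 = 50 - 25 = 25, E2 = 5 + 5 = 10
        assert gk_lambda(ContingencyTable([[20, 5], [5, 20]])) == pytest.approx(0.6)

    def test_bias_corrected_cramers_v(self):
        # hand derivation: phi2 = 0.25, n = 80, shrunk phi2 = 0.25 - 1/79,
        # effective min(r, c) - 1 = 1 - 1/79
        t = ContingencyTable([[30, 10], [10, 30]])
        assert cramers_v(t, bias_correct=True) == pytest.approx(0.4902903, abs=1e-6)
        # correction only shrinks
        assert cramers_v(t, bias_correct=True) < cramers_v(t)

    def test_bias_corrected_clips_at_zero(self):
        # phi2 below its independence expectation -> corrected V = 0
        assert cramers_v(WORKED, bias_correct=True) == 0.0


class TestClosedFormHelpers:
    def test_pearsons_c_from_w(self):
        # c = w / sqrt(1 + w^2); printed-precision checks at n = 1000
        assert round(pearsons_c_from_w(0.0588, 1000), 4) == 0.0587
        assert round(pearsons_c_from_w(0.1288, 1000), 4) == 0.1277

    def test_tschuprows_t_from_w(self):
        # printed-input rounding limits agreement to +/- 1e-4
        assert tschuprows_t_from_w(0.0588, 2, 3) == pytest.approx(0.0495, abs=1e-4)


class TestIdentities:
    """w = sqrt(chi2/n), c = w/sqrt(1+w^2), V = w/sqrt(min(r-1,c-1)),
    T = w/((r-1)(c-1))^(1/4) — on random tables, to machine precision."""

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3), (2, 4), (3, 4), (4, 4)])
    def test_chi_square_family(self, random_table, shape):
        r, c = shape
        for _ in range(40):
            t = random_table(r=r, c=c, n=600)
            stats = t.chi_square()
            w = cohens_w(t)
            assert w == pytest.approx(math.sqrt(stats.chi2 / stats.n), rel=1e-12)
            assert pearsons_c(t) == pytest.approx(w / math.sqrt(1 + w * w), rel=1e-12)
            assert cramers_v(t) == pytest.approx(
                w / math.sqrt(min(r - 1, c - 1)), rel=1e-12
            )
            assert tschuprows_t(t) == pytest.approx(
                w / ((r - 1) * (c - 1)) ** 0.25, rel=1e-12
            )

    def test_gk_tau_equals_phi2_on_2x2(self, random_table):
        for _ in range(50):
            t = random_table(r=2, c=2, n=400)
            assert gk_tau(t) == pytest.approx(t.chi_square().phi2, rel=1e-10)

    def test_u_matches_sklearn_mutual_information(self, random_table):
        # U = I(X;Y) / H(X) with X the row variable
        from scipy.stats import entropy
        from sklearn.metrics import mutual_info_score

        for _ in range(10):
            t = random_table(r=3, c=4, n=300)
            rows, cols = np.nonzero(t.counts)
            reps = t.counts[rows, cols]
            x = np.repeat(rows, reps)
            y = np.repeat(cols, reps)
            h_x = entropy(t.row_totals / t.n)
            ref = mutual_info_score(x, y) / h_x
            assert uncertainty_coefficient(t) == pytest.approx(ref, rel=1e-9)

    def test_u_invariant_to_log_base(self, random_table):
        # ratio form: scaling both entropies by log(2) cancels
        t = random_table(r=2, c=3, n=500)
        a = t.counts.astype(float)
        n = a.sum()
        p_x = a.sum(axis=1) / n
        p_x = p_x[p_x > 0]
        h_x = -np.sum(p_x * np.log2(p_x))
        h_xy = 0.0
        for j in range(a.shape[1]):
            col = a[:, j]
            if col.sum() == 0:
                continue
            p_joint = col / n
            p_cond = col / col.sum()
            nz = p_joint > 0
            h_xy -= np.sum(p_joint[nz] * np.log2(p_cond[nz]))
        assert uncertainty_coefficient(t) == pytest.approx((h_x - h_xy) / h_x, rel=1e-9)

    def test_v_t_c_match_scipy_association(self, random_table):
        from scipy.stats.contingency import association

        for shape in [(2, 3), (3, 4)]:
            t = random_table(*shape, n=700)
            assert cramers_v(t) == pytest.approx(
                association(t.counts, method="cramer"), rel=1e-9
            )
            assert tschuprows_t(t) == pytest.approx(
                association(t.counts, method="tschuprow"), rel=1e-9
            )
            assert pearsons_c(t) == pytest.approx(
                association(t.counts, method="pearson"), rel=1e-9
            )


class TestSymmetries:
    def test_row_permutation_leaves_measures_unchanged(self, random_table):
        t = random_table(r=3, c=4, n=500)
        perm = ContingencyTable(t.counts[[2, 0, 1]])
        for measure in (cramers_v, tschuprows_t, pearsons_c, cohens_w,
                        gk_tau, uncertainty_coefficient, gk_lambda):
            assert measure(perm) == pytest.approx(measure(t), rel=1e-12)

    def test_transpose_preserves_chi_square_family(self, random_table):
        t = random_table(r=2, c=4, n=500)
        for measure in (cramers_v, tschuprows_t, pearsons_c, cohens_w):
            assert measure(t.transpose()) == pytest.approx(measure(t), rel=1e-12)

    def test_direction_argument_flips_orientation(self, random_table):
        t = random_table(r=2, c=4, n=500)
        for measure in (gk_tau, uncertainty_coefficient, gk_lambda):
            assert measure(t, direction="column-given-row") == pytest.approx(
                measure(t.transpose()), rel=1e-12
            )


class TestErrors:
    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cramers_v(ContingencyTable([[1, 2, 3]]))

    def test_constant_dependent_variable(self):
        t = ContingencyTable([[5, 7], [0, 0]])
        with pytest.raises(ValueError, match="tau"):
            gk_tau(t)
        with pytest.raises(ValueError, match="U"):
            uncertainty_coefficient(t)
        with pytest.raises(ValueError, match="lambda"):
            gk_lambda(t)

    def test_compute_all_flags_undefined_as_nan(self):
        vec = compute_all(ContingencyTable([[5, 7], [0, 0]]))
        assert not vec.complete
        assert math.isnan(vec.gk_tau)
        assert math.isnan(vec.uncertainty_u)
        assert math.isnan(vec.gk_lambda)
        # chi-square family still defined on this table
        assert math.isfinite(vec.cohens_w)


class TestComputeAll:
    def test_all_zero_under_independence(self):
        assert np.allclose(compute_all(INDEPENDENT).as_array(), 0.0)

    def test_range_contract(self, random_table):
        for shape in [(2, 2), (2, 3), (3, 4)]:
            vec = compute_all(random_table(*shape, n=400))
            arr = vec.as_array()
            assert np.all(arr >= -1e-12)
            # all but Cohen's w are bounded by 1; w can exceed 1 only for
            # multi-level association, never here
            assert np.all(arr <= 1.0 + 1e-12)
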