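"""Structure of the age-by-stage projection matrix and its eigensystem."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import agestage as ag
from agestage._linalg import vec
from agestage.build import EigenError


class TestVecPermutation:
    @pytest.mark.parametrize("s,omega", [(1, 5), (5, 1), (1, 1)])
    def test_vector_transpose_is_identity(self, s, omega):
        K = ag.vec_permutation_matrix(s, omega)
        assert np.array_equal(K.toarray(), np.eye(s * omega))

    def test_two_by_two_explicit(self):
        K = ag.vec_permutation_matrix(2, 2)
        expect = [[1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 1]]
        assert np.array_equal(K.toarray(), expect)

    @settings(deadline=None, max_examples=40)
    @given(s=st.integers(1, 20), omega=st.integers(1, 50), seed=st.integers(0, 999))
    def test_permutes_vec_to_vec_of_transpose(self, s, omega, seed):
        rng = np.random.default_rng(seed)
        N = rng.standard_normal((s, omega))
        K = ag.vec_permutation_matrix(s, omega)
        assert np.array_equal(K @ vec(N), vec(N.T))

    @settings(deadline=None, max_examples=25)
    @given(s=st.integers(1, 20), omega=st.integers(1, 50))
    def test_permutation_identities(self, s, omega):
        K = ag.vec_permutation_matrix(s, omega)
        eye = np.eye(s * omega)
        assert np.array_equal((K @ K.T).toarray(), eye)
        # transposing the vec-permutation swaps the dimension order
        assert (K.T != ag.vec_permutation_matrix(omega, s)).nnz == 0

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            ag.vec_permutation_matrix(0, 3)


class TestAgeTransitionMatrices:
    def test_age_advance_positions(self):
        D = ag.age_advance_matrix(4).toarray()
        expect = np.zeros((4, 4))
        expect[[1, 2, 3, 3], [0, 1, 2, 3]] = 1  # subdiagonal + open-class corner
        assert np.array_equal(D, expect)

    def test_age_reset_positions(self):
        D = ag.age_reset_matrix(4).toarray()
        assert np.array_equal(D, [[1, 1, 1, 1], [0] * 4, [0] * 4, [0] * 4])

    def test_single_age_class_degenerates_to_one(self):
        assert np.array_equal(ag.age_advance_matrix(1).toarray(), [[1.0]])
        assert np.array_equal(ag.age_reset_matrix(1).toarray(), [[1.0]])

    @pytest.mark.parametrize("omega", [1, 2, 7])
    def test_column_stochastic(self, omega):
        assert np.allclose(ag.age_advance_matrix(omega).sum(axis=0), 1)
        assert np.allclose(ag.age_reset_matrix(omega).sum(axis=0), 1)

    def test_rejects_omega_below_one(self):
        with pytest.raises(ValueError):
            ag.age_advance_matrix(0)


class TestBuildProjection:
    def test_single_stage_collapses_to_leslie_like(self):
        # one stage: the age-by-stage matrix is the classical age-classified
        # matrix with fertility across the first row and survival on the
        # subdiagonal plus the open-class corner
        m = ag.build_stage_set(np.array([[0.6]]), np.array([[1.3]]))
        model = ag.build_projection(m, 4)
        At = model.Atilde.toarray()
        expect = np.zeros((4, 4))
        expect[0, :] = 1.3
        expect[[1, 2, 3, 3], [0, 1, 2, 3]] += 0.6
        assert np.allclose(At, expect)

    def test_toy2_column_of_stage2_age2(self, toy2):
        # a stage-2 age-2 individual survives into stage 2 age 3 and sends
        # offspring into stage 1 age 1
        model = ag.build_projection(toy2, 3)
        At = model.Atilde.toarray()
        col = 1 * 2 + 1  # age class 2, stage 2 (0-based block i=1, stage j=1)
        expect = np.zeros(6)
        expect[2 * 2 + 1] = 0.8  # stage 2, age 3
        expect[0] = 2.0  # stage 1, age 1
        assert np.allclose(At[:, col], expect)

    def test_zero_fertility_leaves_only_survival_term(self, toy2):
        m = ag.build_stage_set(toy2.U, np.zeros((2, 2)))
        model = ag.build_projection(m, 3)
        survival_only = model.MU @ model.blockU
        assert np.allclose(model.Atilde.toarray(), survival_only.toarray())

    def test_two_term_identity(self, lefko5):
        model = ag.build_projection(lefko5, 6)
        K, s = model.K, lefko5.s
        rebuilt = (
            K.T @ model.blockDU @ K @ model.blockU
            + K.T @ model.blockDF @ K @ model.blockF
        )
        assert np.allclose(model.Atilde.toarray(), rebuilt.toarray())

    def test_column_sums_are_survival_plus_offspring(self, lefko5):
        # conservation: each column of Atilde sums to sigma_j + total
        # offspring of stage j, inherited from column-stochastic D_U, D_F
        model = ag.build_projection(lefko5, 9)
        sums = np.asarray(model.Atilde.sum(axis=0)).ravel()
        expect = np.tile(lefko5.sigma + lefko5.F.sum(axis=0), 9)
        assert np.allclose(sums, expect)

    def test_nonnegative(self, lefko5):
        assert (ag.build_projection(lefko5, 12).Atilde < 0).nnz == 0

    def test_dimension_cap(self, lefko5):
        with pytest.raises(ValueError, match="cap"):
            ag.build_projection(lefko5, 10**6)


class TestEigenAnalysis:
    def test_lambda_matches_stage_matrix_for_any_omega(self, lefko5):
        lamA = ag.eigen_analysis(lefko5.A).lam
        for omega in (2, 5, 23):
            lam = ag.eigen_analysis(ag.build_projection(lefko5, omega)).lam
            assert lam == pytest.approx(lamA, abs=1e-10)

    def test_toy2_lambda_closed_form(self, toy2):
        model = ag.build_projection(toy2, 6)
        lam = ag.eigen_analysis(model).lam
        assert lam == pytest.approx((0.8 + np.sqrt(4.64)) / 2, abs=1e-12)

    def test_stage_marginal_of_w_is_stable_stage_distribution(self, lefko5):
        eigA = ag.eigen_analysis(lefko5.A)
        model = ag.build_projection(lefko5, 40)
        eig = ag.eigen_analysis(model)
        marg = eig.stable_structure(lefko5.s, 40).sum(axis=1)
        assert np.allclose(marg, eigA.w, atol=1e-8)

    def test_normalizations(self, lefko5):
        eig = ag.eigen_analysis(ag.build_projection(lefko5, 10))
        assert eig.w.sum() == pytest.approx(1.0)
        assert eig.v @ eig.w == pytest.approx(1.0)
        assert np.all(eig.w >= 0) and np.all(eig.v >= 0)

    def test_residuals_small(self, lefko5):
        model = ag.build_projection(lefko5, 10)
        eig = ag.eigen_analysis(model)
        At = model.Atilde
        assert np.abs(At @ eig.w - eig.lam * eig.w).max() < 1e-10
        assert np.abs(eig.v @ At - eig.lam * eig.v).max() < 1e-10

    def test_closed_form_eigensystem_matches_numeric(self, lefko5):
        # the single-matrix model admits a closed-form eigensystem (used
        # automatically for large dimensions); it must match the generic
        # numeric solve
        from agestage.build import _eigen_uniform

        model = ag.build_projection(lefko5, 18)
        numeric = ag.eigen_analysis(model.Atilde)
        closed = _eigen_uniform(model)
        assert closed.lam == pytest.approx(numeric.lam, abs=1e-12)
        assert np.abs(closed.w - numeric.w).max() < 1e-10
        assert np.abs(closed.v - numeric.v).max() < 1e-8

    def test_analytic_stable_distribution_matches_eigenvector(self, lefko5):
        model = ag.build_projection(lefko5, 12)
        eig = ag.eigen_analysis(model.Atilde)
        W = ag.stable_age_stage_distribution(lefko5, 12)
        assert np.abs(W.reshape(-1, order="F") - eig.w).max() < 1e-10

    def test_imprimitive_cycle_warns_of_degenerate_gap(self):
        # pure 2-cycle: Perron root 1 tied in modulus with -1
        cyc = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="gap"):
            ag.eigen_analysis(cyc)

    def test_no_positive_growth_direction_rejected(self):
        # nilpotent life cycle: all eigenvalues zero, no growth rate
        with pytest.raises(EigenError, match="dominant"):
            ag.eigen_analysis(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestProject:
    def test_eigenvector_grows_by_lambda(self, toy2):
        model = ag.build_projection(toy2, 5)
        eig = ag.eigen_analysis(model)
        traj = ag.project(eig.w, model, 1)
        assert np.allclose(traj[1], eig.lam * eig.w, atol=1e-12)

    def test_zero_stays_zero(self, toy2):
        model = ag.build_projection(toy2, 5)
        traj = ag.project(np.zeros(model.dim), model, 3)
        assert np.all(traj == 0)

    def test_long_run_growth_converges_to_lambda(self, toy2):
        model = ag.build_projection(toy2, 5)
        eig = ag.eigen_analysis(model)
        rng = np.random.default_rng(1)
        traj = ag.project(rng.uniform(0.5, 1.5, model.dim), model, 200)
        totals = traj.sum(axis=1)
        assert totals[-1] / totals[-2] == pytest.approx(eig.lam, abs=1e-8)

    def test_negative_abundance_rejected(self, toy2):
        model = ag.build_projection(toy2, 5)
        with pytest.raises(ValueError, match="nonnegative"):
            ag.project(-np.ones(model.dim), model, 1)


class TestSelectOmega:
    def test_annual_plant_needs_two_classes(self):
        # nobody survives past the first age class
        m = ag.build_stage_set(np.array([[0.0]]), np.array([[2.0]]))
        assert ag.select_omega(m) == 2

    def test_scalar_geometric_tail(self):
        # s=1, sigma=0.5, lambda=1: stable age distribution is geometric
        # with ratio 1/2, so the open-class share is 0.5**(omega-1) and the
        # smallest omega with share <= 0.01 is 8
        m = ag.build_stage_set(np.array([[0.5]]), np.array([[0.5]]))
        assert ag.select_omega(m, coverage=0.99) == 8

    def test_monotone_in_coverage(self, lefko5):
        omegas = [ag.select_omega(lefko5, coverage=c) for c in (0.5, 0.9, 0.99, 0.999)]
        assert omegas == sorted(omegas)

    def test_result_satisfies_and_predecessor_fails(self, lefko5):
        from agestage.build import _tail_mass

        om = ag.select_omega(lefko5, coverage=0.99)
        assert _tail_mass(lefko5, om) <= 0.01
        if om > 2:
            assert _tail_mass(lefko5, om - 1) > 0.01

    def test_cap_reached_raises(self):
        # survival == 1 at lambda == 1: the age distribution never tails off
        m = ag.build_stage_set(np.array([[1.0]]), np.array([[0.0]]))
        with pytest.raises(RuntimeError, match="omega"):
            ag.select_omega(m, omega_max=64)
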