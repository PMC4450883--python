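import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.base import clone
from sklearn.svm import SVC

import mahinge as mh
from conftest import random_iksvm_model


class TestIntersectionKernel:
    def test_self_kernel_is_sum(self):
        assert mh.intersection_kernel([1, 2, 3], [1, 2, 3]) == 6.0

    def test_zero_absorbs(self):
        assert mh.intersection_kernel([0, 0], [5, 7]) == 0.0

    def test_elementwise_minimum(self):
        assert mh.intersection_kernel([1, 4, 2], [3, 1, 2]) == 4.0

    def test_rejects_mismatch_and_negative(self):
        with pytest.raises(ValueError):
            mh.intersection_kernel([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            mh.intersection_kernel([-1, 2], [1, 2])

    @settings(deadline=None, max_examples=50)
    @given(
        x=hnp.arrays(np.float64, 8, elements=st.floats(0, 255)),
        z=hnp.arrays(np.float64, 8, elements=st.floats(0, 255)),
    )
    def test_symmetry_and_bound(self, x, z):
        k = mh.intersection_kernel(x, z)
        assert k == mh.intersection_kernel(z, x)
        assert k <= min(x.sum(), z.sum()) + 1e-9
        assert k >= 0

    def test_gram_matches_pairwise_kernel(self, rng):
        X = rng.uniform(0, 255, (7, 5))
        Z = rng.uniform(0, 255, (4, 5))
        G = mh.intersection_gram(X, Z)
        for i in range(7):
            for j in range(4):
                assert G[i, j] == mh.intersection_kernel(X[i], Z[j])


class TestTraining:
    def test_two_point_problem(self):
        X = np.array([[1.0], [3.0]])
        y = np.array([-1.0, 1.0])
        model = mh.train(X, y, C=100.0)
        assert model.n_support == 2
        assert mh.decide_naive(model, np.array([1.0])) < 0
        assert mh.decide_naive(model, np.array([3.0])) > 0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mh.train(np.ones((4, 2)), np.ones(4))

    def test_non_finite_features_raise(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            mh.train(X, np.array([1, 1, -1, -1]))

    def test_kkt_box_and_equality_constraints(self, rng):
        X = rng.uniform(0, 255, (60, 5))
        y = np.where(X[:, 0] + rng.normal(scale=20, size=60) > 127, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        C = 2.5
        model = mh.train(X, y, C=C)
        # coefficients are alpha * y: |alpha| <= C
        assert np.all(np.abs(model.coefficients) <= C + 1e-9)
        assert abs(model.coefficients.sum()) <= 1e-6

    def test_separated_classes_learned_with_margin(self, rng):
        """Class-dependent means in 65-dim; margin holds for free SVs."""
        n, d, C = 200, 65, 1.0
        y = np.repeat([1.0, -1.0], n // 2)
        X = rng.uniform(40, 60, size=(n, d))
        X[: n // 2] += 60.0  # positive class brighter
        model = mh.train(X, y, C=C)
        h = mh.decide_naive(model, X)
        acc = np.mean(np.sign(h) == y)
        assert acc > 0.9
        # KKT: non-bound support vectors sit on the margin
        h_sv = mh.decide_naive(model, model.support_vectors)
        y_sv = np.sign(model.coefficients)
        alphas = np.abs(model.coefficients)
        free = alphas < C - 1e-6
        assert np.all(h_sv[free] * y_sv[free] >= 1 - 1e-3)


class TestFastTables:
    def test_single_support_vector(self):
        model = mh.IKSVMModel(
            support_vectors=np.array([[2.0, 5.0, 1.0]]),
            coefficients=np.array([0.7]),
            bias=0.0,
            C=1.0,
        )
        t = mh.build_tables(model)
        np.testing.assert_array_equal(t.A[0], 0.0)
        np.testing.assert_array_equal(t.B[1], 0.0)
        np.testing.assert_allclose(t.A[1], 0.7 * np.array([2.0, 5.0, 1.0]))
        np.testing.assert_allclose(t.B[0], 0.7)

    def test_tables_match_bruteforce_partial_sums(self, rng):
        model = random_iksvm_model(rng, m=5, n=3)
        t = mh.build_tables(model)
        X, coef = model.support_vectors, model.coefficients
        for i in range(3):
            order = np.argsort(X[:, i], kind="stable")
            xs, cs = X[order, i], coef[order]
            assert np.all(np.diff(t.sorted_values[:, i]) >= 0)
            for r in range(6):
                assert t.A[r, i] == pytest.approx(np.sum(cs[:r] * xs[:r]), abs=1e-12)
                assert t.B[r, i] == pytest.approx(np.sum(cs[r:]), abs=1e-12)

    def test_b_zero_row_is_dimension_free(self, rng):
        model = random_iksvm_model(rng, m=9, n=4)
        t = mh.build_tables(model)
        total = model.coefficients.sum()
        np.testing.assert_allclose(t.B[0], total, atol=1e-12)
        assert np.ptp(t.B[0]) <= 1e-12

    def test_empty_model_rejected(self):
        model = mh.IKSVMModel(
            support_vectors=np.empty((0, 3)), coefficients=np.empty(0),
            bias=0.0, C=1.0,
        )
        with pytest.raises(ValueError):
            mh.build_tables(model)


class TestDecision:
    def test_naive_on_lone_support_vector(self):
        sv = np.array([[3.0, 1.0, 4.0]])
        model = mh.IKSVMModel(sv, np.array([2.0]), bias=-1.5, C=1.0)
        assert mh.decide_naive(model, sv[0]) == pytest.approx(2.0 * 8.0 - 1.5)

    def test_naive_at_zero_query_returns_bias(self, rng):
        model = random_iksvm_model(rng, m=6, n=4)
        assert mh.decide_naive(model, np.zeros(4)) == pytest.approx(model.bias)

    def test_naive_equals_explicit_expansion(self, rng):
        model = random_iksvm_model(rng, m=6, n=4)
        z = rng.uniform(0, 255, 4)
        expected = model.bias + sum(
            c * mh.intersection_kernel(z, sv)
            for c, sv in zip(model.coefficients, model.support_vectors)
        )
        assert mh.decide_naive(model, z) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("m,n", [(1, 1), (2, 3), (17, 65), (64, 8)])
    def test_fast_matches_naive(self, rng, m, n):
        model = random_iksvm_model(rng, m=m, n=n, with_duplicates=True)
        tables = mh.build_tables(model)
        Z = rng.uniform(0, 255, size=(50, n))
        hn = mh.decide_naive(model, Z)
        hf = mh.decide_fast(tables, model.bias, Z)
        np.testing.assert_allclose(hf, hn, rtol=1e-9, atol=1e-9)

    def test_fast_matches_naive_at_tied_support_values(self, rng):
        model = random_iksvm_model(rng, m=8, n=5)
        tables = mh.build_tables(model)
        z = model.support_vectors[3].copy()  # every z_i on a breakpoint
        assert mh.decide_fast(tables, model.bias, z) == pytest.approx(
            mh.decide_naive(model, z), rel=1e-9
        )

    def test_fast_below_all_support_values(self, rng):
        model = random_iksvm_model(rng, m=8, n=5)
        # enforce the dual equality exactly: sum(alpha y) = 0
        model.coefficients[-1] -= model.coefficients.sum()
        tables = mh.build_tables(model)
        z = np.full(5, -0.0)
        low = mh.decide_fast(tables, model.bias, tables.sorted_values[0] - 1.0)
        assert low == pytest.approx(model.bias, abs=1e-9)
        assert mh.decide_fast(tables, model.bias, z) == pytest.approx(model.bias)

    def test_each_h_i_is_continuous_piecewise_linear(self, rng):
        """h_i is continuous at every breakpoint with slope B between them.

        At the r-th sorted support value v the two adjacent linear pieces
        A[r-1] + t B[r-1] and A[r] + t B[r] must agree at t = v, and
        between breakpoints the evaluated h_i must equal the r-th piece.
        """
        model = random_iksvm_model(rng, m=6, n=1)
        tables = mh.build_tables(model)
        vs = tables.sorted_values[:, 0]
        for r, v in enumerate(vs, start=1):
            left_piece = tables.A[r - 1, 0] + v * tables.B[r - 1, 0]
            right_piece = tables.A[r, 0] + v * tables.B[r, 0]
            assert right_piece == pytest.approx(left_piece, rel=1e-12, abs=1e-9)
        mids = (vs[:-1] + vs[1:]) / 2
        for r, t in enumerate(mids, start=1):
            h = mh.decide_fast(tables, 0.0, np.array([t]))
            assert h == pytest.approx(
                tables.A[r, 0] + t * tables.B[r, 0], rel=1e-12, abs=1e-9
            )

    def test_dimension_mismatch_rejected(self, rng):
        model = random_iksvm_model(rng, m=3, n=4)
        tables = mh.build_tables(model)
        with pytest.raises(ValueError):
            mh.decide_naive(model, np.zeros(5))
        with pytest.raises(ValueError):
            mh.decide_fast(tables, 0.0, np.zeros(5))


class TestClassify:
    def test_sign_convention(self, rng):
        model = random_iksvm_model(rng, m=4, n=3)
        z = rng.uniform(0, 255, 3)
        h = mh.decide_naive(model, z)
        assert mh.classify(model, z) == (1 if h >= 0 else -1)

    def test_zero_decision_maps_to_positive(self):
        model = mh.IKSVMModel(
            support_vectors=np.array([[1.0]]), coefficients=np.array([1.0]),
            bias=-1.0, C=1.0,
        )
        assert mh.decide_naive(model, np.array([1.0])) == 0.0
        assert mh.classify(model, np.array([1.0])) == 1


class TestEstimator:
    def test_sklearn_protocol(self, rng):
        est = mh.IntersectionKernelSVC(C=2.0)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        X = rng.uniform(0, 10, (40, 3))
        y = np.where(X[:, 0] > 5, "hinge", "background")
        est.fit(X, y)
        assert set(est.predict(X)) <= {"hinge", "background"}
        assert est.score(X, y) > 0.8

    def test_decision_function_uses_exact_fast_path(self, rng):
        X = rng.uniform(0, 255, (50, 6))
        y = np.where(X[:, 0] > 127, 1, -1)
        est = mh.IntersectionKernelSVC().fit(X, y)
        hf = est.decision_function(X)
        hn = mh.decide_naive(est.model_, X)
        np.testing.assert_allclose(hf, hn, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_baseline_kernels_match_reference_svc(self, rng, kernel):
        X = rng.uniform(0, 255, (60, 4))
        y = np.where(X[:, 0] + X[:, 1] > 255, 1, -1)
        est = mh.IntersectionKernelSVC(kernel=kernel, tol=1e-4).fit(X, y)
        ref = SVC(kernel=kernel, C=1.0, gamma="scale", tol=1e-4).fit(X, y)
        np.testing.assert_allclose(
            est.decision_function(X), ref.decision_function(X), rtol=1e-6, atol=1e-8
        )


class TestSerialization:
    def test_json_roundtrip_preserves_decisions(self, rng):
        model = random_iksvm_model(rng, m=7, n=6)
        back = mh.IKSVMModel.from_json(model.to_json())
        Z = rng.uniform(0, 255, (10, 6))
        np.testing.assert_array_equal(
            mh.decide_naive(back, Z), mh.decide_naive(model, Z)
        )
        tables = mh.build_tables(back)  # tables rebuild cleanly on load
        np.testing.assert_allclose(
            mh.decide_fast(tables, back.bias, Z), mh.decide_naive(model, Z),
            rtol=1e-9,
        )

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError):
            mh.IKSVMModel.from_dict({"schema": "something-else"})
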