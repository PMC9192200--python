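"""PLS-DA core: SIMPLS correctness, VIP, LOO-CV, LV selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endospec.plsda import (
    EncodingError,
    encode_classes,
    loo_cv,
    nipals_pls,
    plsda_fit,
    plsda_predict,
    select_n_lv,
    vip_scores,
    _simpls_batch,
)


def _blob_data(rng, n_per=10, sep=6.0, m=5):
    """Three well-separated Gaussian blobs."""
    centers = sep * np.array([[1, 0], [0, 1], [-1, -1]], dtype=float)
    X = np.vstack([
        rng.normal(size=(n_per, m)) + np.pad(c, (0, m - 2)) for c in centers
    ])
    labels = ["E"] * n_per + ["NE"] * n_per + ["C"] * n_per
    return X, labels


class TestEncoding:
    def test_one_hot_respects_declared_order(self):
        enc = encode_classes(["E", "C", "NE"], ("E", "NE", "C"))
        np.testing.assert_array_equal(
            enc.Y, [[1, 0, 0], [0, 0, 1], [0, 1, 0]]
        )

    def test_rows_sum_to_one(self):
        enc = encode_classes(["E"] * 3 + ["C"] * 2)
        np.testing.assert_array_equal(enc.Y.sum(axis=1), 1.0)

    def test_single_class_still_encodes(self):
        enc = encode_classes(["E", "E"], ("E", "NE", "C"))
        assert enc.Y[:, 0].sum() == 2

    @pytest.mark.parametrize("labels", [[], ["X"]])
    def test_bad_labels_rejected(self, labels):
        with pytest.raises(EncodingError):
            encode_classes(labels)


class TestSIMPLS:
    def test_separable_classes_perfect_training_fit(self, rng):
        X, labels = _blob_data(rng)
        model = plsda_fit(X, labels, A=2, scaler_kind="autoscale")
        _, pred = plsda_predict(model, X)
        assert (pred == np.asarray(labels, dtype=object)).all()

    def test_univariate_single_y_equals_ols_slope(self, rng):
        # with one x, one y and one LV, the PLS coefficient is the
        # least-squares slope of the centred data
        x = rng.normal(size=(30, 1))
        y = 2.5 * x + rng.normal(0, 0.1, size=(30, 1))
        xc, yc = x - x.mean(), y - y.mean()
        R, _, Q, _ = _simpls_batch(xc[None], yc[None], 1)
        coef = (R[0] @ Q[0].T).item()
        slope = ((xc.T @ yc) / (xc.T @ xc)).item()
        assert coef == pytest.approx(slope, rel=1e-10)

    def test_full_rank_equals_least_squares(self, rng):
        X, labels = _blob_data(rng, m=5)
        enc = encode_classes(labels)
        model = plsda_fit(X, enc, A=5, scaler_kind="center")
        scores, _ = plsda_predict(model, X)
        Xc = X - X.mean(axis=0)
        B = np.linalg.lstsq(Xc, enc.Y - enc.Y.mean(axis=0), rcond=None)[0]
        oracle = Xc @ B + enc.Y.mean(axis=0)
        np.testing.assert_allclose(scores, oracle, atol=1e-8)

    def test_nipals_cross_check_single_response(self, rng):
        X = rng.normal(size=(25, 8))
        y = (X[:, :2] @ [1.0, -2.0] + rng.normal(0, 0.3, 25))[:, None]
        Xc, yc = X - X.mean(0), y - y.mean()
        for A in (1, 2, 4):
            R, _, Q, _ = _simpls_batch(Xc[None], yc[None], A)
            np.testing.assert_allclose(
                R[0] @ Q[0].T, nipals_pls(Xc, yc, A), atol=1e-6
            )

    def test_nipals_cross_check_full_rank_multiresponse(self, rng):
        # at full rank both algorithms reproduce the least-squares fit,
        # so their predictions must coincide even for multi-column Y
        X, labels = _blob_data(rng, m=4)
        enc = encode_classes(labels)
        Xc = X - X.mean(0)
        Yc = enc.Y - enc.Y.mean(0)
        R, _, Q, _ = _simpls_batch(Xc[None], Yc[None], 4)
        np.testing.assert_allclose(
            Xc @ (R[0] @ Q[0].T), Xc @ nipals_pls(Xc, Yc, 4), atol=1e-6
        )

    def test_deterministic(self, rng):
        X, labels = _blob_data(rng)
        a = plsda_fit(X, labels, A=3)
        b = plsda_fit(X.copy(), list(labels), A=3)
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_tie_breaks_to_first_class(self):
        model = plsda_fit(np.eye(4), ["E", "E", "NE", "NE"], A=1, scaler_kind="center")
        model.coef[:] = 0.0
        model.y_mean[:] = [0.5, 0.5, 0.0]
        _, pred = plsda_predict(model, np.zeros((3, 4)))
        assert (pred == "E").all()

    def test_dimension_mismatch_rejected(self, rng):
        X, labels = _blob_data(rng)
        model = plsda_fit(X, labels, A=2)
        with pytest.raises(ValueError, match="expected"):
            plsda_predict(model, X[:, :3])

    def test_too_many_lvs_rejected(self, rng):
        X, labels = _blob_data(rng, n_per=3, m=4)
        with pytest.raises(ValueError):
            plsda_fit(X, labels, A=9)


class TestVIP:
    def test_normalization_identity(self, rng):
        X, labels = _blob_data(rng, m=7)
        for A in (1, 2, 4):
            v = vip_scores(plsda_fit(X, labels, A=A))
            assert np.sum(v**2) == pytest.approx(7.0, rel=1e-10)

    def test_informative_variable_has_max_vip(self, rng):
        n = 60
        labels = ["E"] * 20 + ["NE"] * 20 + ["C"] * 20
        X = rng.normal(size=(n, 10))
        X[:, 3] += np.repeat([0.0, 3.0, 6.0], 20)  # implanted signal
        v = vip_scores(plsda_fit(X, labels, A=2))
        assert np.argmax(v) == 3 and v[3] > 1.0

    def test_duplicated_columns_symmetric(self, rng):
        base = rng.normal(size=(30, 1)) + np.repeat([0.0, 2.0, 4.0], 10)[:, None]
        X = np.tile(base, (1, 4))
        labels = ["E"] * 10 + ["NE"] * 10 + ["C"] * 10
        v = vip_scores(plsda_fit(X, labels, A=1, scaler_kind="center"))
        np.testing.assert_allclose(v, 1.0, rtol=1e-8)


class TestLOOCV:
    def test_separable_classes_zero_errors(self, rng):
        # mean-centred scaling keeps the absolute margin; autoscaling would
        # re-normalize the between-class variance away
        X, labels = _blob_data(rng, sep=10.0)
        cv = loo_cv(X, labels, A=2, scaler_kind="center")
        assert cv.misclassified == 0
        assert cv.accuracy == 1.0

    def test_matches_manual_refit_oracle(self, rng):
        # the vectorised LOO must agree with explicitly refitting a model
        # on each n-1 subset and predicting the held-out row
        X, labels = _blob_data(rng, n_per=6, sep=2.0, m=4)
        cv = loo_cv(X, labels, A=2, scaler_kind="autoscale")
        for i in range(len(labels)):
            keep = [j for j in range(len(labels)) if j != i]
            model = plsda_fit(X[keep], [labels[j] for j in keep], A=2)
            scores, pred = plsda_predict(model, X[i][None])
            np.testing.assert_allclose(cv.scores[i], scores[0], atol=1e-10)
            assert cv.predicted[i] == pred[0]

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(12)
        n = 60
        X = rng.normal(size=(n, 8))
        accs = []
        for _ in range(20):
            labels = list(np.asarray(["E", "NE", "C"]).repeat(20))
            rng.shuffle(labels)
            accs.append(loo_cv(X, labels, A=2).accuracy)
        assert 0.23 <= np.mean(accs) <= 0.43

    def test_minimum_sample_boundary(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        cv = loo_cv(X, ["E", "NE", "C", "E"], A=1, scaler_kind="center")
        assert len(cv.predicted) == 4
        assert 2 in cv.flagged_folds  # class C vanishes from fold 2's training set

    def test_rowlocal_pretreatment_applied(self, rng):
        X, labels = _blob_data(rng, sep=10.0, m=40)
        called = {}

        def pre(M):
            called["shape"] = M.shape
            return M * 2.0

        cv = loo_cv(X, labels, A=2, scaler_kind="center", pretreatment=pre)
        assert called["shape"] == X.shape
        assert cv.misclassified == 0


class TestSelectNLV:
    def test_single_latent_direction_selects_one(self, rng):
        # rank-1 class signal separating two classes with a wide margin:
        # one LV already yields zero LOO errors, so the most parsimonious
        # model wins (a 3-class argmax needs a second LV geometrically,
        # because the middle class has no linear covariance with t)
        n = 30
        t = np.repeat([0.0, 6.0], 15) + rng.normal(0, 0.2, n)
        X = np.outer(t, rng.normal(size=6) + 2.0) + rng.normal(0, 1.0, (n, 6))
        labels = ["E"] * 15 + ["NE"] * 15
        A, trace = select_n_lv(X, labels, A_max=5, scaler_kind="center")
        assert trace[0] == 0
        assert A == 1

    def test_plateau_takes_smallest(self):
        rng = np.random.default_rng(21)
        X, labels = _blob_data(rng, sep=12.0)
        A, trace = select_n_lv(X, labels, A_max=6, scaler_kind="center")
        # first index achieving the minimum is returned
        assert trace[A - 1] == trace.min()
        assert (trace[: A - 1] > trace.min()).all()

    def test_pure_noise_chooses_first_minimum(self):
        # on noise the misclassification trace jitters; the contract is
        # that the returned A is the first (most parsimonious) minimum
        rng = np.random.default_rng(22)
        X = rng.normal(size=(45, 8))
        labels = ["E"] * 15 + ["NE"] * 15 + ["C"] * 15
        A, trace = select_n_lv(X, labels, A_max=6)
        assert trace[A - 1] == trace.min()
        assert (trace[: A - 1] > trace[A - 1]).all()


@given(seed=st.integers(0, 2**16), a=st.integers(1, 4))
@settings(max_examples=20, deadline=None)
def test_vip_normalization_property(seed, a):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(20, 6))
    labels = ["E"] * 7 + ["NE"] * 7 + ["C"] * 6
    v = vip_scores(plsda_fit(X, labels, A=a))
    assert np.sum(v**2) == pytest.approx(6.0, rel=1e-8)
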