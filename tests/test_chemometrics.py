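import numpy as np
import pytest

from irripls.chemometrics import (
    ModelMetrics,
    Partition,
    apply_scaling,
    autoscale,
    compute_metrics,
    cross_validate,
    fit_pls,
    inverse_scale,
    spxy_partition,
)


class TestAutoscale:
    def test_columns_standardised(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(40, 6))
        Xs, params = autoscale(X)
        assert np.abs(Xs.mean(axis=0)).max() < 1e-12
        assert np.abs(Xs.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_three_point_column(self):
        Xs, _ = autoscale(np.array([1.0, 2.0, 3.0]))
        assert Xs == pytest.approx([-1.0, 0.0, 1.0])

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4)) * 7 + 2
        Xs, params = autoscale(X)
        assert np.abs(inverse_scale(Xs, params) - X).max() < 1e-10

    def test_constant_column_named(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="wind"):
            autoscale(X, columns=("t_mean", "wind_dir"))


def spxy_oracle(X, y, n_ms):
    """Naive max–min SPXY selection, written independently with plain loops."""
    n = len(X)
    dx = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)])
    dy = np.array([[abs(y[i] - y[j]) for j in range(n)] for i in range(n)])
    d = dx / dx.max() + dy / dy.max()
    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                best, pair = d[i, j], (i, j)
    selected = list(pair)
    while len(selected) < n_ms:
        cand_best, pick = -1.0, None
        for k in range(n):
            if k in selected:
                continue
            dmin = min(d[k, s] for s in selected)
            if dmin > cand_best:
                cand_best, pick = dmin, k
        selected.append(pick)
    return sorted(selected)


class TestSPXY:
    def test_fraction_one_leaves_test_set_empty(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(8, 3)), rng.normal(size=8)
        part = spxy_partition(X, y, fraction=1.0)
        assert part.test_set.size == 0
        assert sorted(part.model_set) == list(range(8))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle_on_five_point_toys(self, seed):
        rng = np.random.default_rng(seed)
        X, y = rng.normal(size=(5, 2)), rng.normal(size=5)
        part = spxy_partition(X, y, fraction=0.6)
        assert list(part.model_set) == spxy_oracle(X, y, 3)

    def test_extreme_pair_always_in_model_set(self):
        rng = np.random.default_rng(7)
        X, y = rng.normal(size=(30, 4)), rng.normal(size=30)
        dx = np.linalg.norm(X[:, None] - X[None], axis=-1)
        dy = np.abs(y[:, None] - y[None])
        d = dx / dx.max() + dy / dy.max()
        i, j = np.unravel_index(np.argmax(d), d.shape)
        part = spxy_partition(X, y, fraction=0.5)
        assert {i, j} <= set(part.model_set)

    def test_split_sizes_follow_rounding(self):
        rng = np.random.default_rng(8)
        X, y = rng.normal(size=(31, 5)), rng.normal(size=31)
        part = spxy_partition(X, y, fraction=0.8)
        assert part.model_set.size == 25 and part.test_set.size == 6

    def test_deterministic_and_disjoint(self):
        rng = np.random.default_rng(9)
        X, y = rng.normal(size=(20, 3)), rng.normal(size=20)
        p1 = spxy_partition(X, y, 0.7)
        p2 = spxy_partition(X, y, 0.7)
        assert np.array_equal(p1.model_set, p2.model_set)
        assert set(p1.model_set).isdisjoint(p1.test_set)
        assert len(p1.model_set) + len(p1.test_set) == 20

    def test_permutation_covariance(self):
        rng = np.random.default_rng(10)
        X, y = rng.normal(size=(12, 3)), rng.normal(size=12)
        perm = rng.permutation(12)
        base = spxy_partition(X, y, 0.5)
        shuffled = spxy_partition(X[perm], y[perm], 0.5)
        assert set(perm[shuffled.model_set]) == set(base.model_set)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            spxy_partition(np.ones((5, 2)), np.arange(5.0), 0.6)


class TestPLS:
    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X = rng.normal(size=(20, 6))
            y = rng.normal(size=20)
            Xs, _ = autoscale(X)
            ys, _ = autoscale(y)
            fit = fit_pls(Xs, ys, 6)
            beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]
            assert np.abs(fit.predict(Xs) - Xs @ beta).max() < 1e-8

    def test_single_informative_column_fits_with_one_lv(self):
        # with mutually orthogonal predictors, a response proportional to one
        # column is captured exactly by the first latent vector
        rng = np.random.default_rng(12)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 5)))
        ys = 3.0 * Q[:, 2]
        fit = fit_pls(Q, ys, 1)
        rmsec = np.sqrt(((fit.predict(Q) - ys) ** 2).mean())
        assert rmsec < 1e-10

    def test_orthonormal_x_one_lv_coef_proportional_to_xty(self):
        rng = np.random.default_rng(13)
        Q, _ = np.linalg.qr(rng.normal(size=(20, 4)))
        y = rng.normal(size=20)
        fit = fit_pls(Q, y, 1)
        xty = Q.T @ y
        ratio = fit.coef / xty
        assert np.ptp(ratio) < 1e-10

    def test_rmsec_monotone_in_lv_count(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=25)
        Xs, _ = autoscale(X)
        ys, _ = autoscale(y)
        rmses = []
        for a in range(1, 9):
            fit = fit_pls(Xs, ys, a)
            rmses.append(np.sqrt(((fit.predict(Xs) - ys) ** 2).mean()))
        assert all(a >= b - 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=30) * 0.5
        Xs, _ = autoscale(X)
        ys, _ = autoscale(y)
        for a in (1, 3, 5):
            fit = fit_pls(Xs, ys, a)
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(Xs, ys)
            assert np.abs(fit.coef - ref.coef_.ravel()).max() < 1e-10

    def test_explained_variance_sums_below_one(self):
        rng = np.random.default_rng(16)
        Xs, _ = autoscale(rng.normal(size=(20, 5)))
        ys, _ = autoscale(rng.normal(size=20))
        fit = fit_pls(Xs, ys, 4)
        assert 0 < fit.explained_x_variance.sum() <= 1 + 1e-12

    def test_invalid_inputs_rejected(self):
        Xs = np.eye(4)
        ys = np.arange(4.0)
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls(Xs, ys, 5)
        bad = Xs.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_pls(bad, ys, 2)


def loo_rmsecv_oracle(X, y, n_lv):
    """Hand-rolled leave-one-out fold loop (independent of cross_validate)."""
    errs = []
    for i in range(len(y)):
        tr = [j for j in range(len(y)) if j != i]
        Xs, xp = autoscale(X[tr])
        ys, yp = autoscale(y[tr])
        fit = fit_pls(Xs, ys, n_lv)
        pred = inverse_scale(fit.predict(apply_scaling(X[[i]], xp)), yp)
        errs.append((pred[0] - y[i]) ** 2)
    return float(np.sqrt(np.mean(errs)))


class TestCrossValidate:
    def test_noise_free_linear_data_rmsecv_near_zero(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(15, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 4.0
        rmsecv = cross_validate(X, y, max_lv=3, scheme="loo")
        assert rmsecv[2] < 1e-8

    def test_always_non_negative(self):
        rng = np.random.default_rng(18)
        X, y = rng.normal(size=(12, 4)), rng.normal(size=12)
        assert (cross_validate(X, y, 4) >= 0).all()

    def test_matches_hand_rolled_fold_loop(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        rmsecv = cross_validate(X, y, max_lv=1, scheme="loo")
        assert rmsecv[0] == pytest.approx(loo_rmsecv_oracle(X, y, 1), abs=1e-10)

    def test_contiguous_blocks_scheme(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(20, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=20) * 0.1
        rmsecv = cross_validate(X, y, max_lv=3, scheme="blocks", n_blocks=4)
        assert rmsecv.shape == (3,) and np.isfinite(rmsecv).all()

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            cross_validate(np.eye(5), np.arange(5.0), 2, scheme="bootstrap")


class TestMetrics:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(obs, obs)
        assert m.bias == 0 and m.rmse == 0 and m.r == pytest.approx(1.0)
        assert m.rpd_is_infinite

    def test_constant_offset_has_zero_sep(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(obs, obs + 0.7)
        assert m.bias == pytest.approx(0.7)
        assert m.sep == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(0.7)

    def test_four_point_hand_computation(self):
        # e = (0.1, -0.1, 0.2, -0.2): values below from the direct formulas
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        m = compute_metrics(obs, pred)
        assert m.bias == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(0.025), abs=1e-12)
        assert m.sep == pytest.approx(np.sqrt(0.1 / 3), abs=1e-12)
        assert m.r == pytest.approx(4.7 / np.sqrt(5 * 4.5), abs=1e-9)
        assert m.rpd == pytest.approx(np.sqrt(5 / 3) / np.sqrt(0.025), abs=1e-9)

    def test_sep_identity(self):
        rng = np.random.default_rng(21)
        obs = rng.normal(size=50)
        pred = obs + rng.normal(0.3, 0.5, size=50)
        m = compute_metrics(obs, pred)
        n = 50
        assert m.sep**2 == pytest.approx(n / (n - 1) * (m.rmse**2 - m.bias**2), abs=1e-9)

    def test_reference_sd_override(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.5, 2.5, 3.5])
        m = compute_metrics(obs, pred, reference_sd=2.0)
        assert m.rpd == pytest.approx(2.0 / 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.arange(3.0), np.arange(4.0))
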