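import numpy as np
import pytest

from brixvis import larsselect as ls
from brixvis import plsr
from brixvis import synthetic_data as sd
from brixvis import pipeline as pl


def random_instance(seed, n=30, p=60, sparsity=5, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[rng.choice(p, sparsity, replace=False)] = rng.normal(size=sparsity) * 2
    y = X @ beta + rng.normal(size=n) * noise
    return X, y


def cd_lasso(Xs, ys, lam, max_iter=100_000, tol=1e-14):
    """Coordinate-descent lasso oracle for (1/2n)||y-Xb||^2 + lam*|b|_1."""
    n, p = Xs.shape
    b = np.zeros(p)
    col_sq = (Xs**2).sum(axis=0)
    r = ys.copy()
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = Xs[:, j] @ r + col_sq[j] * b[j]
            new = np.sign(rho) * max(abs(rho) - n * lam, 0.0) / col_sq[j]
            if new != b[j]:
                r += Xs[:, j] * (b[j] - new)
                delta = max(delta, abs(new - b[j]))
                b[j] = new
        if delta < tol:
            break
    return b


def kkt_violation(Xs, ys, b, lam):
    n = Xs.shape[0]
    g = Xs.T @ (ys - Xs @ b) / n
    active = b != 0
    v = 0.0
    if active.any():
        v = max(v, np.abs(g[active] - lam * np.sign(b[active])).max())
    if (~active).any():
        v = max(v, max(np.abs(g[~active]).max() - lam, 0.0))
    return v


class TestStandardize:
    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = rng.normal(size=20)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        np.testing.assert_allclose(Xs, X, atol=1e-12)

    def test_scale_equivariance_of_active_sets(self):
        X, y = random_instance(1)
        X2 = X.copy()
        X2[:, 3] *= 10.0
        p1 = ls.lars_path_l1(*ls.standardize_for_path(X, y)[:2])
        p2 = ls.lars_path_l1(*ls.standardize_for_path(X2, y)[:2])
        for lam in [0.5, 0.1, 0.02]:
            a1 = np.flatnonzero(ls.solution_at_lambda(p1, lam))
            a2 = np.flatnonzero(ls.solution_at_lambda(p2, lam))
            np.testing.assert_array_equal(a1, a2)

    def test_constant_column_excluded_with_warning(self):
        X, y = random_instance(2, p=6)
        X[:, 4] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            Xs, _, info = ls.standardize_for_path(X, y, wavelengths=np.arange(6.0))
        assert Xs.shape[1] == 5
        assert 4 not in info.kept

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            ls.standardize_for_path(np.ones((10, 3)), np.arange(10.0))


class TestLarsPathL1:
    def test_orthonormal_soft_thresholding(self):
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(16, 8)))
        y = rng.normal(size=16)
        path = ls.lars_path_l1(Q, y)
        z = Q.T @ y
        for lam in [0.005, 0.01, 0.02, 0.05]:
            expected = np.sign(z) * np.maximum(np.abs(z) - 16 * lam, 0.0)
            np.testing.assert_allclose(ls.solution_at_lambda(path, lam),
                                       expected, atol=1e-8)

    def test_above_lambda_max_all_zero(self):
        X, y = random_instance(4)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        lam_max = np.abs(Xs.T @ ys).max() / Xs.shape[0]
        assert path.lambda_max == pytest.approx(lam_max)
        assert np.all(ls.solution_at_lambda(path, lam_max * 1.01) == 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_coordinate_descent(self, seed):
        X, y = random_instance(seed)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        for frac in [0.5, 0.2, 0.1, 0.05, 0.02]:
            lam = frac * path.lambda_max
            b = ls.solution_at_lambda(path, lam)
            oracle = cd_lasso(Xs, ys, lam)
            np.testing.assert_allclose(b, oracle, atol=1e-6)

    def test_lambda_strictly_decreasing(self):
        X, y = random_instance(5)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        assert np.all(np.diff(path.lambdas) < 0)

    def test_first_knot_empty_active_set(self):
        X, y = random_instance(6)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        assert path.active_sets[0].size == 0
        assert np.all(path.coefs[0] == 0)

    def test_orthogonal_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.normal(size=(20, 10)))
        y = rng.normal(size=20)
        path = ls.lars_path_l1(Q, y)
        sizes = [np.count_nonzero(ls.solution_at_lambda(path, lam))
                 for lam in np.linspace(path.lambda_max, 1e-6, 30)]
        assert np.all(np.diff(sizes) >= 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ls.lars_path_l1(np.array([[1.0, np.nan]]), np.array([1.0]))


class TestSolutionAtLambda:
    def test_knot_exact(self):
        X, y = random_instance(8)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        k = len(path.lambdas) // 2
        np.testing.assert_allclose(ls.solution_at_lambda(path, path.lambdas[k]),
                                   path.coefs[k], atol=1e-12)

    def test_midpoint_satisfies_kkt(self):
        X, y = random_instance(9)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        k = len(path.lambdas) // 2
        lam = 0.5 * (path.lambdas[k] + path.lambdas[k + 1])
        b = ls.solution_at_lambda(path, lam)
        assert kkt_violation(Xs, ys, b, lam) < 1e-6

    def test_lambda_zero_gives_least_squares(self):
        X, y = random_instance(10, n=40, p=10)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        expected, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        np.testing.assert_allclose(ls.solution_at_lambda(path, 0.0), expected, atol=1e-6)


class TestL2Augment:
    def test_endpoint_matches_closed_form_ridge(self):
        X, y = random_instance(11, n=40, p=10)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        n, p = Xs.shape
        for lam in [0.05, 0.3, 1.0]:
            Xa, ya = ls.lars_l2_augment(Xs, ys, lam)
            path = ls.lars_path_l1(Xa, ya)
            expected = np.linalg.solve(Xs.T @ Xs + n * lam * np.eye(p), Xs.T @ ys)
            np.testing.assert_allclose(path.coefs[-1], expected, atol=1e-6)

    def test_large_lambda_shrinks_to_zero(self):
        X, y = random_instance(12, n=40, p=8)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        Xa, ya = ls.lars_l2_augment(Xs, ys, 1e6)
        path = ls.lars_path_l1(Xa, ya)
        assert np.abs(path.coefs[-1]).max() < 1e-4

    def test_augmented_shape(self):
        X, y = random_instance(13, n=20, p=7)
        Xs, ys, _ = ls.standardize_for_path(X, y)
        Xa, ya = ls.lars_l2_augment(Xs, ys, 0.1)
        assert Xa.shape == (27, 7) and ya.shape == (27,)

    def test_nonpositive_lambda_rejected(self):
        X, y = random_instance(14, n=10, p=6, sparsity=2)
        with pytest.raises(ValueError):
            ls.lars_l2_augment(X, y, 0.0)


class TestSelectWavelengths:
    def test_band_recovery_small(self):
        cfg = sd.SimulationConfig(seed=0)
        scans, bg, truth, _ = sd.generate_dataset(sd.PROVENCE, cfg, "O2")
        ds = pl.aggregate_to_dataset(scans, bg, truth.ssc)
        lam = ls.choose_lambda_l1_cv(ds.X, ds.y, seed=0)
        sel = ls.select_wavelengths(ds.X, ds.y, lam, cv_seed=0,
                                    wavelengths=ds.wavelengths)
        for lo, hi in truth.band_windows():
            assert any(lo <= w <= hi for w in sel.wavelengths_nm)

    def test_empty_selection_error(self):
        X, y = random_instance(15)
        with pytest.raises(ls.EmptySelectionError, match="smaller lambda"):
            ls.select_wavelengths(X, y, 1e6, penalty="L1")

    def test_pure_noise_sparse(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(30, 200))
        y = rng.normal(size=30)
        lam = ls.choose_lambda_l1_cv(X, y, seed=0)
        try:
            sel = ls.select_wavelengths(X, y, lam, penalty="L1")
            count = sel.count
        except ls.EmptySelectionError:
            count = 0
        assert count <= 30  # path cardinality bound; far below p=200

    def test_original_scale_coefficients_predict(self):
        X, y = random_instance(17, noise=0.01)
        sel = ls.select_wavelengths(X, y, 0.01, penalty="L1")
        pred = X[:, sel.indices] @ sel.coefficients + sel.intercept
        # compare against the standardized-scale lasso prediction
        Xs, ys, info = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        b = ls.solution_at_lambda(path, 0.01)
        np.testing.assert_allclose(pred, Xs @ b + info.y_mean, atol=1e-8)

    def test_l2_selection_finite_count(self):
        X, y = random_instance(18, n=40, p=30)
        sel = ls.select_wavelengths(X, y, 0.1, penalty="L2", cv_seed=0, max_steps=20)
        assert 0 < sel.count <= 30
        assert sel.penalty == "L2"

    def test_kkt_certified_l1(self):
        X, y = random_instance(19)
        Xs, ys, info = ls.standardize_for_path(X, y)
        path = ls.lars_path_l1(Xs, ys)
        lam = 0.1 * path.lambda_max
        sel = ls.select_wavelengths(X, y, lam, penalty="L1")
        b = np.zeros(Xs.shape[1])
        b_std = sel.coefficients * info.x_sd[sel.indices]
        b[np.searchsorted(info.kept, sel.indices)] = b_std
        assert kkt_violation(Xs, ys, b, lam) < 1e-6


class TestScanLambda:
    def test_noiseless_rp_one(self, quiet_config):
        cfg = sd.SimulationConfig(
            seed=3, grid=quiet_config.grid, noise_sd=0.0, background_noise_sd=0.0,
            scatter_gain_range=(1.0, 1.0), saturation_prob=0.0, band_jitter_sd=0.0,
            interferent_bands=())
        scans, bg, truth, _ = sd.generate_dataset(sd.PROVENCE, cfg, "O2")
        ds = pl.aggregate_to_dataset(scans, bg, truth.ssc)
        split = pl.split_dataset(ds.n, seed=0)
        tab = ls.scan_lambda(ds.X[split.calibration], ds.y[split.calibration],
                             ds.X[split.prediction], ds.y[split.prediction],
                             [1e-5, 1e-4], wavelengths=ds.wavelengths)
        assert np.all(tab["Rp"] > 1 - 1e-6)

    def test_lambda_max_only_flagged_empty(self):
        X, y = random_instance(20)
        split_at = 20
        with pytest.warns(UserWarning, match="empty at every lambda"):
            tab = ls.scan_lambda(X[:split_at], y[:split_at], X[split_at:], y[split_at:],
                                 [1e6])
        assert len(tab) == 1 and tab["n_variables"].iloc[0] == 0
        assert np.isnan(tab["Rp"].iloc[0])

    def test_duplicates_deduplicated(self):
        X, y = random_instance(21, noise=0.1)
        tab = ls.scan_lambda(X[:20], y[:20], X[20:], y[20:], [0.05, 0.05, 0.01, 0.05])
        assert list(tab["lambda"]) == [0.05, 0.01]


class TestSerialization:
    def test_round_trip(self, tmp_path):
        X, y = random_instance(22)
        sel = ls.select_wavelengths(X, y, 0.05, penalty="L1",
                                    wavelengths=np.linspace(560, 1072, 60))
        path = tmp_path / "sel.json"
        ls.save_selection(sel, path)
        loaded = ls.load_selection(path)
        assert loaded.penalty == sel.penalty and loaded.count == sel.count
        np.testing.assert_allclose(loaded.coefficients, sel.coefficients)
        np.testing.assert_array_equal(loaded.indices, sel.indices)
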