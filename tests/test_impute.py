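"""Imputation methods: forced examples, brute-force oracles, contract properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metamiss import (
    IntensityMatrix,
    SimulationConfig,
    ampute_mcar,
    ampute_mnar_lod,
    generate_complete,
    impute,
    impute_constant,
    impute_forest,
    impute_iterative_pca,
    impute_knn,
    impute_qrilc,
    impute_random,
    impute_svd,
    list_methods,
    nrmse,
)
from metamiss.exceptions import ConfigError, ImputationError, UnknownMethodError

from conftest import random_masked_matrix


def _mat(values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    return IntensityMatrix(values, mask)


class TestConstant:
    @pytest.mark.parametrize("strategy,expected", [
        ("mean", 3.0), ("half_min", 1.0), ("min", 2.0), ("zero", 0.0),
    ])
    def test_forced_single_column(self, strategy, expected):
        mat = _mat([[2.0], [np.nan], [4.0]])
        res = impute_constant(mat, strategy)
        assert res.completed[1, 0] == expected
        assert res.n_imputed == 1

    def test_median_forced(self):
        mat = _mat([[1.0], [3.0], [10.0], [np.nan]])
        assert impute_constant(mat, "median").completed[3, 0] == 3.0

    def test_statistics_are_per_column(self):
        mat = _mat([[1.0, 100.0], [np.nan, np.nan], [3.0, 300.0]])
        res = impute_constant(mat, "mean")
        assert res.completed[1, 0] == 2.0 and res.completed[1, 1] == 200.0

    def test_fully_missing_column_errors(self):
        mat = _mat([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ImputationError, match="met_2"):
            impute_constant(mat, "mean")
        # zero strategy tolerates it
        assert impute_constant(mat, "zero").completed[0, 1] == 0.0


class TestRandom:
    def test_degenerate_range_exact(self):
        mat = _mat([[5.0], [5.0], [np.nan], [5.0]])
        assert impute_random(mat, seed=3).completed[2, 0] == 5.0

    def test_within_observed_range(self):
        mat = random_masked_matrix(1, n=30, m=8, frac=0.3)
        res = impute_random(mat, seed=9)
        lo = np.nanmin(mat.values, axis=0)
        hi = np.nanmax(mat.values, axis=0)
        i, j = np.nonzero(mat.mask)
        assert ((res.completed[i, j] >= lo[j]) & (res.completed[i, j] <= hi[j])).all()

    def test_uniform_mean_clt(self):
        values = np.full((10001, 1), np.nan)
        values[0, 0], values[1, 0] = 0.0, 1.0
        mat = _mat(values)
        res = impute_random(mat, seed=21)
        assert 0.47 <= res.completed[2:, 0].mean() <= 0.53

    def test_seed_determinism(self):
        mat = random_masked_matrix(2)
        a = impute_random(mat, seed=4).completed
        b = impute_random(mat, seed=4).completed
        assert np.array_equal(a, b)
        assert not np.array_equal(a, impute_random(mat, seed=5).completed)


def knn_bruteforce(mat: IntensityMatrix, k: int) -> np.ndarray:
    """Literal re-statement of the KNN rule with explicit loops (raw scale)."""
    vals, mask = mat.values, mat.mask
    n, m = vals.shape
    out = vals.copy()
    for i in range(n):
        for j in range(m):
            if not mask[i, j]:
                continue
            dists = []
            for other in range(n):
                if other == i:
                    continue
                shared = ~mask[i] & ~mask[other]
                if not shared.any():
                    continue
                d2 = ((vals[i, shared] - vals[other, shared]) ** 2).sum() / shared.sum()
                dists.append((d2, other))
            donors = [o for _, o in sorted(dists) if not mask[o, j]][:k]
            if donors:
                out[i, j] = vals[donors, j].mean()
            else:
                out[i, j] = np.nanmean(vals[:, j])
    return out


class TestKnn:
    def test_identical_twin_wins(self):
        values = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [50.0, 60.0, 70.0]])
        res = impute_knn(_mat(values), k=1, log_transform=False)
        assert res.completed[1, 2] == 3.0

    def test_k_covers_all_other_samples(self):
        rng = np.random.default_rng(3)
        values = np.exp(rng.normal(3, 1, size=(8, 5)))
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 0] = True  # the only missing cell; all other samples observe m1
        mat2 = IntensityMatrix(values, mask)
        res = impute_knn(mat2, k=50, log_transform=False)
        assert res.completed[0, 0] == pytest.approx(mat2.values[1:, 0].mean())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        mat = random_masked_matrix(seed, n=6, m=5, frac=0.25)
        res = impute_knn(mat, k=2, log_transform=False)
        assert np.allclose(res.completed, knn_bruteforce(mat, 2), rtol=1e-12)

    def test_k_below_one_rejected(self):
        with pytest.raises(ConfigError):
            impute_knn(random_masked_matrix(0), k=0)


class TestSvd:
    def test_rank_one_matrix_recovered(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([2.0, 1.0, 4.0])
        values = np.outer(u, v)
        mask = np.zeros_like(values, dtype=bool)
        mask[2, 1] = True
        mat = IntensityMatrix(np.where(mask, np.nan, values), mask)
        res = impute_svd(mat, rank=1, tol=1e-10, max_iter=500, log_transform=False)
        assert res.completed[2, 1] == pytest.approx(values[2, 1], rel=1e-6)
        assert res.converged

    def test_huge_tol_single_iteration(self):
        mat = random_masked_matrix(4)
        res = impute_svd(mat, rank=1, tol=1e9, log_transform=False)
        assert res.n_iterations == 1 and res.converged

    def test_convergence_changes_shrink(self):
        # the imputed-entry update magnitude settles monotonically (after burn-in)
        truth = generate_complete(SimulationConfig(40, 12, latent_rank=2, noise_sd=0.05, seed=5))
        amp = ampute_mcar(truth, 0.15, seed=6)
        deltas = []
        prev = None
        for iters in range(1, 9):
            res = impute_svd(amp.amputed, rank=2, tol=0.0, max_iter=iters)
            cur = res.completed[amp.amputed.mask]
            if prev is not None:
                deltas.append(np.linalg.norm(cur - prev))
            prev = cur
        assert all(b <= a * 1.001 for a, b in zip(deltas[2:], deltas[3:]))

    def test_rank_too_large_rejected(self):
        with pytest.raises(ConfigError):
            impute_svd(random_masked_matrix(0, n=5, m=4), rank=4)


class TestIterativePca:
    def test_ncomp_zero_is_column_mean(self):
        mat = random_masked_matrix(7)
        a = impute_iterative_pca(mat, ncomp=0, log_transform=False).completed
        b = impute_constant(mat, "mean").completed
        assert np.allclose(a, b)

    def test_recovery_on_low_noise_rank2(self):
        rel_errs = []
        for seed in range(10):
            truth = generate_complete(
                SimulationConfig(60, 15, latent_rank=2, noise_sd=0.01, seed=seed))
            amp = ampute_mcar(truth, 0.1, seed=seed + 50)
            res = impute_iterative_pca(amp.amputed, ncomp=2)
            i, j = np.nonzero(amp.amputed.mask)
            rel = np.abs(res.completed[i, j] - truth.values[i, j]) / truth.values[i, j]
            rel_errs.append(np.median(rel))
        assert np.median(rel_errs) < 0.05

    def test_unregularized_limit_matches_svd(self):
        # on columns with similar spread, reg=0 EM-PCA and SVD completion agree
        truth = generate_complete(
            SimulationConfig(50, 12, latent_rank=2, noise_sd=0.02, seed=3))
        amp = ampute_mcar(truth, 0.1, seed=4)
        a = impute_iterative_pca(amp.amputed, ncomp=2, regularization=0.0,
                                 tol=1e-8, max_iter=500).completed
        b = impute_svd(amp.amputed, rank=2, tol=1e-8, max_iter=500).completed
        i, j = np.nonzero(amp.amputed.mask)
        rel = np.abs(a[i, j] - b[i, j]) / np.abs(b[i, j])
        assert np.median(rel) < 0.02

    def test_auto_ncomp_tracks_latent_rank(self):
        truth = generate_complete(SimulationConfig(80, 30, latent_rank=3, noise_sd=0.1, seed=9))
        amp = ampute_mcar(truth, 0.15, seed=10)
        auto = impute_iterative_pca(amp.amputed)  # ncomp="auto"
        fixed = impute_iterative_pca(amp.amputed, ncomp=3)
        v_auto = nrmse(truth.values, auto.completed, amp.amputed.mask).value
        v_fixed = nrmse(truth.values, fixed.completed, amp.amputed.mask).value
        assert v_auto <= v_fixed * 1.25

    def test_ncomp_too_large_rejected(self):
        with pytest.raises(ConfigError):
            impute_iterative_pca(random_masked_matrix(0, n=5, m=4), ncomp=4)


class TestForest:
    def test_duplicated_column_functional_dependence(self):
        rng = np.random.default_rng(0)
        base = np.exp(rng.normal(3, 1, size=(200, 3)))
        values = np.column_stack([base, base[:, 0]])
        mask = np.zeros_like(values, dtype=bool)
        mask[rng.choice(200, size=30, replace=False), 3] = True
        mat = IntensityMatrix(np.where(mask, np.nan, values), mask)
        res = impute_forest(mat, n_trees=100, seed=1)
        i = np.nonzero(mask[:, 3])[0]
        rel = np.abs(res.completed[i, 3] - values[i, 3]) / values[i, 3]
        assert np.median(rel) < 0.10

    def test_no_missing_returns_unchanged(self, complete_matrix):
        res = impute_forest(complete_matrix, n_trees=10)
        assert res.n_iterations == 0
        assert np.array_equal(res.completed, complete_matrix.values)

    def test_seed_determinism(self):
        mat = random_masked_matrix(5, n=25, m=5, frac=0.2)
        a = impute_forest(mat, n_trees=15, seed=7).completed
        b = impute_forest(mat, n_trees=15, seed=7).completed
        assert np.array_equal(a, b)

    def test_single_column_rejected(self):
        with pytest.raises(ConfigError):
            impute_forest(_mat([[1.0], [np.nan], [2.0]]))


class TestQrilc:
    def test_imputed_below_observed_minimum(self):
        truth = generate_complete(SimulationConfig(60, 10, seed=11))
        amp = ampute_mnar_lod(truth, 0.2, seed=12)
        res = impute_qrilc(amp.amputed, seed=13)
        mins = np.nanmin(amp.amputed.values, axis=0)
        i, j = np.nonzero(amp.amputed.mask)
        assert (res.completed[i, j] <= mins[j] + 1e-9).all()

    def test_left_tail_property_on_censored_lognormal(self):
        rng = np.random.default_rng(14)
        col = np.exp(rng.normal(0, 1, size=400))
        t = np.quantile(col, 0.2)
        mask = (col < t)[:, None]
        mat = IntensityMatrix(np.where(mask, np.nan, col[:, None]), mask)
        res = impute_qrilc(mat, seed=15)
        imputed_logs = np.log(res.completed[mask[:, 0], 0])
        observed_logs = np.log(col[~mask[:, 0]])
        assert imputed_logs.mean() < observed_logs.mean()

    def test_tune_sigma_shrinks_spread(self):
        truth = generate_complete(SimulationConfig(200, 4, seed=16))
        amp = ampute_mnar_lod(truth, 0.3, seed=17)
        wide = impute_qrilc(amp.amputed, tune_sigma=1.0, seed=18)
        narrow = impute_qrilc(amp.amputed, tune_sigma=0.01, seed=18)
        j = 0
        mis = amp.amputed.mask[:, j]
        sd_wide = np.log(wide.completed[mis, j]).std()
        sd_narrow = np.log(narrow.completed[mis, j]).std()
        assert sd_narrow < 0.1 * max(sd_wide, 1e-9) + 1e-9

    def test_too_few_observations_falls_back(self):
        values = np.array([[2.0, 1.0], [4.0, 2.0], [np.nan, 3.0],
                           [np.nan, 4.0], [np.nan, 5.0]])
        mat = _mat(values)
        with pytest.warns(UserWarning, match="fewer than 4"):
            res = impute_qrilc(mat, seed=19)
        assert np.allclose(res.completed[2:, 0], 1.0)  # half of observed min 2.0


class TestRegistryAndDispatch:
    def test_registry_contents(self):
        methods = {m.name: m for m in list_methods()}
        assert len(methods) == 11
        assert methods["random"].family == "random" and methods["random"].stochastic
        assert sum(m.family == "constant" for m in methods.values()) == 5

    def test_every_method_runs_on_small_fixture(self):
        mat = random_masked_matrix(8, n=12, m=6, frac=0.2)
        fast = {"forest": {"n_trees": 5, "max_iter": 2}}
        for spec in list_methods():
            res = impute(mat, spec.name, params=fast.get(spec.name), seed=1)
            assert not np.isnan(res.completed).any()
            assert res.n_imputed == mat.n_missing

    def test_dispatch_identity_with_direct_call(self):
        mat = random_masked_matrix(9)
        assert np.array_equal(
            impute(mat, "mean").completed, impute_constant(mat, "mean").completed
        )

    def test_unknown_method_lists_names(self):
        with pytest.raises(UnknownMethodError, match="qrilc"):
            impute(random_masked_matrix(0), "foo")

    def test_invalid_param_named(self):
        with pytest.raises(ConfigError, match="bogus"):
            impute(random_masked_matrix(0), "knn", params={"bogus": 3})

    def test_derived_seed_recorded(self):
        mat = random_masked_matrix(10)
        res = impute(mat, "random")
        assert res.seed is not None
        again = impute(mat, "random", seed=res.seed)
        assert np.array_equal(res.completed, again.completed)

    def test_verbose_false_silent(self, capfd):
        mat = random_masked_matrix(11, n=15, m=4)
        impute(mat, "forest", params={"n_trees": 5, "max_iter": 2}, seed=1, verbose=False)
        out, err = capfd.readouterr()
        assert out == "" and err == ""

    def test_verbose_true_reports_progress(self, capfd):
        mat = random_masked_matrix(11, n=15, m=4)
        impute(mat, "forest", params={"n_trees": 5, "max_iter": 2}, seed=1, verbose=True)
        assert "iteration" in capfd.readouterr().err


@pytest.mark.parametrize("method", [m.name for m in list_methods()])
def test_observed_cells_preserved_bit_exact(method):
    mat = random_masked_matrix(12, n=14, m=6, frac=0.25)
    params = {"forest": {"n_trees": 5, "max_iter": 2}}.get(method)
    res = impute(mat, method, params=params, seed=2)
    obs = ~mat.mask
    assert np.array_equal(res.completed[obs], mat.values[obs])


@pytest.mark.parametrize("method", ["zero", "min", "half_min", "mean", "median", "knn"])
def test_scale_equivariance(method):
    mat = random_masked_matrix(13, n=12, m=5)
    scaled = IntensityMatrix(mat.values * 3.5, mat.mask.copy())
    a = impute(mat, method).completed
    b = impute(scaled, method).completed
    assert np.allclose(b, 3.5 * a, rtol=1e-10)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000),
       st.sampled_from(["mean", "median", "min", "knn", "random", "qrilc"]))
def test_completion_contract_random_instances(seed, method):
    mat = random_masked_matrix(seed, n=10, m=5, frac=0.3)
    res = impute(mat, method, seed=seed)
    assert not np.isnan(res.completed).any()
    obs = ~mat.mask
    assert np.array_equal(res.completed[obs], mat.values[obs])
    assert res.n_imputed == mat.mask.sum()
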