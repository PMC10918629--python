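"""Native imputation methods for metabolomics intensity matrices.

Eleven methods sit behind one contract: an imputer receives an
:class:`~metamiss.data.IntensityMatrix` and returns a completed matrix in
which every observed cell is preserved bit-exactly and every masked cell is
replaced by an estimate.  Methods never modify non-missing data points.

Families
--------
constant    zero / min / half_min / mean / median per metabolite
random      uniform draw within the metabolite's observed range (baseline)
neighbour   sample-wise K nearest neighbours, pairwise-complete Euclidean
low_rank    iterative truncated-SVD matrix completion
iterative_model
            regularized iterative PCA (EM with ridge-style singular-value
            shrinkage) and missForest-style iterative random forests
censored    QRILC: quantile regression imputation of left-censored data

Model-based methods (svd, iterative_pca, forest, qrilc) work on the log
scale by default, since metabolite intensities are approximately log-normal;
constant, random and KNN work on the raw scale.  The flag is recorded in the
result and can be overridden per call.

Stochastic methods (random, forest, qrilc) take an explicit seed — there is
no hidden global random state.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import IntensityMatrix
from .exceptions import ConfigError, ImputationError, UnknownMethodError

__all__ = [
    "ImputationMethod",
    "ImputationResult",
    "impute",
    "impute_constant",
    "impute_random",
    "impute_knn",
    "impute_svd",
    "impute_iterative_pca",
    "impute_forest",
    "impute_qrilc",
    "list_methods",
    "register_method",
]


@dataclass(frozen=True)
class ImputationMethod:
    """Registry entry: a public method name with its family and defaults."""

    name: str
    family: str
    defaults: dict = field(default_factory=dict)
    stochastic: bool = False


@dataclass
class ImputationResult:
    """A completed matrix plus bookkeeping about how it was produced."""

    completed: np.ndarray
    n_imputed: int
    converged: bool
    n_iterations: int
    method: str
    seed: int | None = None
    log_transformed: bool = False

    def to_matrix(self, template: IntensityMatrix) -> IntensityMatrix:
        """Wrap the completed values with the template's labels (empty mask)."""
        return IntensityMatrix(
            self.completed,
            np.zeros_like(template.mask),
            list(template.sample_ids),
            list(template.metabolite_ids),
        )


# --------------------------------------------------------------------------
# helpers


def _check_columns_have_observations(matrix: IntensityMatrix, method: str) -> None:
    empty = np.nonzero(~(~matrix.mask).any(axis=0))[0]
    if empty.size:
        names = [matrix.metabolite_ids[j] for j in empty]
        raise ImputationError(
            f"method {method!r} cannot impute fully missing metabolite(s): {names}"
        )


def _log_observed(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Log-transform, guarding against observed zeros with a half-minimum
    pseudocount (metabolomics convention for sub-LOD signals)."""
    obs = values[~mask]
    positive = obs[obs > 0]
    offset = 0.0
    if obs.size and obs.min() <= 0:
        offset = float(positive.min()) / 2.0 if positive.size else 1.0
    return np.log(values + offset), offset


def _finish(
    matrix: IntensityMatrix,
    filled: np.ndarray,
    method: str,
    *,
    converged: bool = True,
    n_iterations: int = 0,
    seed: int | None = None,
    log_transformed: bool = False,
) -> ImputationResult:
    """Assemble a result, restoring observed cells bit-exactly."""
    completed = matrix.values.copy()
    completed[matrix.mask] = filled[matrix.mask]
    return ImputationResult(
        completed=completed,
        n_imputed=int(matrix.mask.sum()),
        converged=converged,
        n_iterations=n_iterations,
        method=method,
        seed=seed,
        log_transformed=log_transformed,
    )


# --------------------------------------------------------------------------
# constant family


_CONSTANT_STRATEGIES = ("zero", "min", "half_min", "mean", "median")


def impute_constant(matrix: IntensityMatrix, strategy: str = "min") -> ImputationResult:
    """Replace each metabolite's missing cells by a per-column constant.

    ``min`` and ``half_min`` are classical LOD heuristics: a value that was
    not detected is assumed to sit at (or below) the smallest detected
    intensity of that metabolite.
    """
    if strategy not in _CONSTANT_STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}; expected one of {_CONSTANT_STRATEGIES}")
    vals, mask = matrix.values, matrix.mask
    if strategy != "zero":
        _check_columns_have_observations(matrix, strategy)
    filled = np.zeros_like(vals)
    if strategy != "zero":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns handled above
            if strategy == "min":
                col = np.nanmin(vals, axis=0)
            elif strategy == "half_min":
                col = np.nanmin(vals, axis=0) / 2.0
            elif strategy == "mean":
                col = np.nanmean(vals, axis=0)
            else:
                col = np.nanmedian(vals, axis=0)
        filled = np.broadcast_to(col, vals.shape).copy()
    return _finish(matrix, filled, strategy)


# --------------------------------------------------------------------------
# random baseline


def impute_random(matrix: IntensityMatrix, seed: int = 0) -> ImputationResult:
    """Baseline: draw each missing cell uniformly within its metabolite's
    observed [min, max] range."""
    _check_columns_have_observations(matrix, "random")
    vals, mask = matrix.values, matrix.mask
    lo = np.nanmin(vals, axis=0)
    hi = np.nanmax(vals, axis=0)
    rng = np.random.default_rng(seed)
    draws = lo + (hi - lo) * rng.random(vals.shape)
    return _finish(matrix, draws, "random", seed=seed)


# --------------------------------------------------------------------------
# K nearest neighbours


def _knn_distances(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Euclidean distances between samples, scaled
    by the number of shared (both observed) metabolites.  Pairs sharing no
    metabolite get distance +inf."""
    x = np.where(mask, 0.0, vals)
    obs = (~mask).astype(float)
    sq = x**2
    # sum over shared features of (x_i - x_k)^2, expanded so masked cells drop out
    cross = x @ x.T
    a = sq @ obs.T
    shared = obs @ obs.T
    d2 = a + a.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared > 0, np.maximum(d2, 0.0) / shared, np.inf)
    return d2


def impute_knn(
    matrix: IntensityMatrix, k: int = 5, log_transform: bool = True
) -> ImputationResult:
    """Sample-wise KNN under pairwise-complete Euclidean distance.

    For a missing cell (i, j), the k nearest other samples that observe
    metabolite j contribute their unweighted mean; with fewer than k eligible
    neighbours all of them are used, and with none the column mean steps in.
    Neighbour ties are broken by sample order, making the method
    deterministic.

    Distances are computed on the log scale by default: on raw intensities
    the Euclidean distance is dominated by the handful of highest-abundance
    metabolites, which degrades neighbour selection on log-normal data to the
    point of losing against plain column-mean imputation.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    _check_columns_have_observations(matrix, "knn")
    mask = matrix.mask
    vals, offset = (
        _log_observed(matrix.values, mask) if log_transform else (matrix.values, 0.0)
    )
    n = vals.shape[0]
    d2 = _knn_distances(vals, mask)
    np.fill_diagonal(d2, np.inf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(vals, axis=0)
    filled = np.zeros_like(vals)
    # argsort on (distance, index): numpy argsort is stable, so ties keep sample order
    neighbour_order = np.argsort(d2, axis=1, kind="stable")
    for i, j in zip(*np.nonzero(mask)):
        donors = []
        for cand in neighbour_order[i]:
            if np.isinf(d2[i, cand]):
                break
            if not mask[cand, j]:
                donors.append(cand)
                if len(donors) == k:
                    break
        filled[i, j] = vals[donors, j].mean() if donors else col_mean[j]
    if log_transform:
        filled = np.exp(filled) - offset
    return _finish(matrix, filled, "knn", log_transformed=log_transform)


# --------------------------------------------------------------------------
# iterative low-rank completion (SVD-impute and regularized iterative PCA)


def _iterative_lowrank(
    vals: np.ndarray,
    mask: np.ndarray,
    rank: int,
    regularization: float,
    standardize: bool,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool, int]:
    """Shared EM-style loop: refill missing cells from a (shrunken) rank-r
    reconstruction of the column-centred (optionally standardized) completed
    matrix until the imputed entries stabilise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(vals, axis=0)
    x = np.where(mask, col_mean[None, :], vals)
    if rank == 0:
        return x, True, 0
    prev = x[mask].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = x.mean(axis=0)
        if standardize:
            sd = x.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            sd = np.ones_like(mu)
        z = (x - mu) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        if regularization > 0 and s.size > rank:
            sigma2 = float(np.mean(s[rank:] ** 2))
            shrunk = s[:rank] * np.maximum(s[:rank] ** 2 - regularization * sigma2, 0.0) / np.where(
                s[:rank] > 0, s[:rank] ** 2, 1.0
            )
        else:
            shrunk = s[:rank]
        recon = (u[:, :rank] * shrunk) @ vt[:rank] * sd + mu
        x = np.where(mask, recon, vals)
        cur = x[mask]
        denom = max(float(np.linalg.norm(prev)), 1e-12)
        change = float(np.linalg.norm(cur - prev)) / denom
        prev = cur.copy()
        if change < tol:
            converged = True
            break
    return x, converged, it


def impute_svd(
    matrix: IntensityMatrix,
    rank: int = 2,
    tol: float = 1e-4,
    max_iter: int = 100,
    log_transform: bool = True,
) -> ImputationResult:
    """Iterative truncated-SVD matrix completion (SVDimpute).

    Missing cells start at the column mean; each iteration reconstructs the
    column-centred matrix at the given rank and refills the missing cells,
    until the relative change of the imputed entries drops below ``tol``.
    """
    n, m = matrix.values.shape
    if not 1 <= rank <= min(n, m) - 1:
        raise ConfigError(f"rank must lie in [1, min(dims)-1={min(n, m) - 1}]")
    _check_columns_have_observations(matrix, "svd")
    vals, offset = (
        _log_observed(matrix.values, matrix.mask) if log_transform else (matrix.values, 0.0)
    )
    x, converged, it = _iterative_lowrank(
        vals, matrix.mask, rank, regularization=0.0, standardize=False, tol=tol, max_iter=max_iter
    )
    filled = np.exp(x) - offset if log_transform else x
    return _finish(
        matrix, filled, "svd", converged=converged, n_iterations=it, log_transformed=log_transform
    )


def _select_ncomp(
    vals: np.ndarray,
    mask: np.ndarray,
    regularization: float,
    max_ncomp: int = 8,
    holdout_fraction: float = 0.05,
) -> int:
    """Choose the number of components by hold-out cross-validation.

    A fixed 5% of the observed cells (never emptying a column below two
    observations) is additionally masked; candidate ranks are scored by the
    standardized squared error of their reconstruction on the held-out cells.
    The hold-out draw uses a fixed internal seed, keeping the method a
    deterministic function of its input.
    """
    n, m = vals.shape
    rng = np.random.default_rng(0)
    holdout = np.zeros_like(mask)
    for j in range(m):
        rows = np.nonzero(~mask[:, j])[0]
        budget = min(max(int(round(holdout_fraction * rows.size)), 1), rows.size - 2)
        if budget > 0:
            holdout[rng.choice(rows, size=budget, replace=False), j] = True
    if not holdout.any():
        return 2
    cv_mask = mask | holdout
    sd = np.array([vals[~mask[:, j], j].std() or 1.0 for j in range(m)])
    candidates = range(1, min(max_ncomp, n - 1, m - 1) + 1)
    best, best_err = 1, np.inf
    for c in candidates:
        x, _, _ = _iterative_lowrank(
            vals, cv_mask, c, regularization, standardize=True, tol=1e-3, max_iter=30
        )
        err = float(np.mean(((x[holdout] - vals[holdout]) / sd[np.nonzero(holdout)[1]]) ** 2))
        if err < best_err - 1e-12:
            best, best_err = c, err
    return best


def impute_iterative_pca(
    matrix: IntensityMatrix,
    ncomp: int | str = "auto",
    regularization: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    log_transform: bool = True,
) -> ImputationResult:
    """Regularized iterative PCA (EM-PCA) imputation.

    Works on column-standardized data and shrinks each retained singular
    value ridge-style toward the mean residual variance of the discarded
    components, damping the overfitting of plain SVD completion when noise is
    appreciable.  ``ncomp="auto"`` (the default) picks the number of
    components by hold-out cross-validation, mirroring how EM-PCA is used in
    practice; ``ncomp=0`` degenerates to column-mean imputation.
    """
    n, m = matrix.values.shape
    if ncomp != "auto" and not 0 <= int(ncomp) <= min(n, m) - 1:
        raise ConfigError(f"ncomp must lie in [0, min(dims)-1={min(n, m) - 1}]")
    if not 0.0 <= regularization <= 1.0:
        raise ConfigError("regularization must lie in [0, 1]")
    _check_columns_have_observations(matrix, "iterative_pca")
    vals, offset = (
        _log_observed(matrix.values, matrix.mask) if log_transform else (matrix.values, 0.0)
    )
    if ncomp == "auto":
        ncomp = _select_ncomp(vals, matrix.mask, regularization)
    x, converged, it = _iterative_lowrank(
        vals,
        matrix.mask,
        int(ncomp),
        regularization=regularization,
        standardize=True,
        tol=tol,
        max_iter=max_iter,
    )
    filled = np.exp(x) - offset if log_transform else x
    return _finish(
        matrix,
        filled,
        "iterative_pca",
        converged=converged,
        n_iterations=it,
        log_transformed=log_transform,
    )


# --------------------------------------------------------------------------
# missForest-style iterative random forest


def impute_forest(
    matrix: IntensityMatrix,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
    log_transform: bool = True,
    verbose: bool = False,
) -> ImputationResult:
    """missForest-style imputation: iteratively regress each metabolite on
    all others with a random forest, visiting metabolites in increasing
    missing-fraction order, until the normalized change of the imputed values
    increases (the previous iterate is returned) or ``max_iter`` is reached.
    """
    from sklearn.ensemble import RandomForestRegressor

    if matrix.n_metabolites < 2:
        raise ConfigError("forest imputation needs at least 2 metabolites")
    _check_columns_have_observations(matrix, "forest")
    mask = matrix.mask
    if not mask.any():
        return _finish(matrix, matrix.values.copy(), "forest", n_iterations=0, seed=seed,
                       log_transformed=log_transform)
    vals, offset = (
        _log_observed(matrix.values, matrix.mask) if log_transform else (matrix.values, 0.0)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(vals, axis=0)
    x = np.where(mask, col_mean[None, :], vals)
    cols = np.nonzero(mask.any(axis=0))[0]
    cols = cols[np.argsort(mask[:, cols].mean(axis=0), kind="stable")]
    ss = np.random.SeedSequence(seed)
    prev_x = x.copy()
    prev_gamma = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_x = x.copy()
        for rank_in_pass, j in enumerate(cols):
            rows_obs = ~mask[:, j]
            rows_mis = mask[:, j]
            other = np.delete(np.arange(x.shape[1]), j)
            rf_seed = int(
                np.random.SeedSequence(
                    entropy=ss.entropy, spawn_key=(it, int(rank_in_pass))
                ).generate_state(1)[0]
                % (2**31)
            )
            rf = RandomForestRegressor(n_estimators=n_trees, random_state=rf_seed, n_jobs=1)
            rf.fit(new_x[rows_obs][:, other], new_x[rows_obs, j])
            new_x[rows_mis, j] = rf.predict(new_x[rows_mis][:, other])
        num = float(((new_x[mask] - x[mask]) ** 2).sum())
        den = max(float((new_x[mask] ** 2).sum()), 1e-12)
        gamma = num / den
        if verbose:
            print(f"forest iteration {it}: gamma={gamma:.3e}", file=sys.stderr)
        if gamma >= prev_gamma:
            x = prev_x  # stopping rule fired: keep the previous iterate
            converged = True
            it -= 1
            break
        prev_gamma = gamma
        prev_x = x.copy()
        x = new_x
    filled = np.exp(x) - offset if log_transform else x
    return _finish(
        matrix,
        filled,
        "forest",
        converged=converged or it == max_iter,
        n_iterations=it,
        seed=seed,
        log_transformed=log_transform,
    )


# --------------------------------------------------------------------------
# QRILC: quantile regression imputation of left-censored data


def impute_qrilc(
    matrix: IntensityMatrix,
    tune_sigma: float = 1.0,
    seed: int = 0,
    log_transform: bool = True,
) -> ImputationResult:
    """Left-censored imputation for LOD-type missingness.

    Per metabolite, on the log scale: treat missing cells as censored below
    the observed minimum, fit a Gaussian to the observed (upper) part by
    regressing observed order statistics on standard-normal quantiles over
    the observed probability range, then draw the missing values from that
    Gaussian truncated above at the observed minimum.  ``tune_sigma`` scales
    the spread of the draws (1 = the fitted sd; smaller values shrink the
    draws toward the truncated mean).
    """
    if not 0.0 < tune_sigma <= 1.0:
        raise ConfigError("tune_sigma must lie in (0, 1]")
    _check_columns_have_observations(matrix, "qrilc")
    vals_raw, mask = matrix.values, matrix.mask
    vals, offset = _log_observed(vals_raw, mask) if log_transform else (vals_raw, 0.0)
    rng = np.random.default_rng(seed)
    filled = np.zeros_like(vals_raw)
    for j in range(vals.shape[1]):
        mis = mask[:, j]
        if not mis.any():
            continue
        obs = np.sort(vals[~mis, j])
        n_obs = obs.size
        if n_obs < 4:
            warnings.warn(
                f"metabolite {matrix.metabolite_ids[j]!r} has fewer than 4 observed "
                "values; falling back to half-minimum imputation",
                stacklevel=2,
            )
            raw_min = np.exp(obs.min()) - offset if log_transform else obs.min()
            filled[mis, j] = raw_min / 2.0
            continue
        pi = mis.mean()  # censored share
        # observed order statistics live on the probability range (pi, 1)
        p = pi + (1.0 - pi) * (np.arange(1, n_obs + 1) - 0.5) / n_obs
        z = stats.norm.ppf(p)
        slope, intercept = np.polyfit(z, obs, 1)
        sigma = max(float(slope), 1e-9)
        mu = float(intercept)
        upper = float(obs.min())
        scale = sigma * tune_sigma
        b = (upper - mu) / scale
        if b < -8.0:
            # far left tail: the truncated normal collapses onto the bound;
            # b - Z is approximately Exp(|b|) there, and this avoids the
            # underflow region of the exact sampler
            z = b - rng.exponential(1.0 / abs(b), size=int(mis.sum()))
        else:
            z = stats.truncnorm.rvs(
                a=b - 39.0, b=b, loc=0.0, scale=1.0, size=int(mis.sum()), random_state=rng
            )
        draws = mu + scale * z
        filled[mis, j] = np.exp(draws) - offset if log_transform else draws
    return _finish(
        matrix, filled, "qrilc", seed=seed, log_transformed=log_transform
    )


# --------------------------------------------------------------------------
# registry and dispatcher


def _make_registry() -> dict:
    reg: dict[str, tuple[ImputationMethod, object]] = {}

    def add(name, family, defaults, stochastic, fn):
        reg[name] = (ImputationMethod(name, family, defaults, stochastic), fn)

    for strat in _CONSTANT_STRATEGIES:
        add(strat, "constant", {}, False,
            lambda mat, _s=strat, **kw: impute_constant(mat, strategy=_s))
    add("random", "random", {}, True, lambda mat, seed=0, **kw: impute_random(mat, seed=seed))
    add("knn", "neighbour", {"k": 5, "log_transform": True}, False,
        lambda mat, **kw: impute_knn(mat, **kw))
    add("svd", "low_rank", {"rank": 2, "tol": 1e-4, "max_iter": 100, "log_transform": True},
        False, lambda mat, **kw: impute_svd(mat, **kw))
    add("iterative_pca", "iterative_model",
        {"ncomp": "auto", "regularization": 1.0, "tol": 1e-4, "max_iter": 100,
         "log_transform": True},
        False, lambda mat, **kw: impute_iterative_pca(mat, **kw))
    add("forest", "iterative_model",
        {"n_trees": 100, "max_iter": 10, "log_transform": True}, True,
        lambda mat, seed=0, verbose=False, **kw: impute_forest(
            mat, seed=seed, verbose=verbose, **kw))
    add("qrilc", "censored", {"tune_sigma": 1.0, "log_transform": True}, True,
        lambda mat, seed=0, **kw: impute_qrilc(mat, seed=seed, **kw))
    return reg


_REGISTRY = _make_registry()
_SEED_PARAMS = {"seed"}


def list_methods() -> list[ImputationMethod]:
    """All registered methods, in stable registration order."""
    return [entry[0] for entry in _REGISTRY.values()]


def register_method(
    name: str, fn, family: str = "custom", defaults: dict | None = None, stochastic: bool = False
) -> None:
    """Register an additional method (e.g. for benchmarking experiments).

    ``fn(matrix, **params) -> ImputationResult`` must honour the contract of
    never modifying observed cells.
    """
    if name in _REGISTRY:
        raise ConfigError(f"method {name!r} already registered")
    _REGISTRY[name] = (ImputationMethod(name, family, defaults or {}, stochastic), fn)


def unregister_method(name: str) -> None:
    _REGISTRY.pop(name, None)


def impute(
    matrix: IntensityMatrix,
    method: str,
    params: dict | None = None,
    verbose: bool = False,
    seed: int | None = None,
) -> ImputationResult:
    """Dispatch to a registered method with defaults overlaid by ``params``.

    Stochastic methods derive a seed when none is given; it is recorded in
    the result so the run can be reproduced.  ``verbose=False`` (the default)
    suppresses all progress output.
    """
    if method not in _REGISTRY:
        raise UnknownMethodError(
            f"unknown method {method!r}; valid names: {', '.join(_REGISTRY)}"
        )
    spec, fn = _REGISTRY[method]
    params = dict(params or {})
    unknown = set(params) - set(spec.defaults) - _SEED_PARAMS - {"verbose"}
    if unknown and spec.family != "custom":
        raise ConfigError(
            f"invalid parameter(s) {sorted(unknown)} for method {method!r}; "
            f"valid: {sorted(spec.defaults)}"
        )
    kwargs = dict(spec.defaults)
    kwargs.update(params)
    if spec.stochastic:
        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
            if verbose:
                print(f"impute[{method}]: derived seed {seed}", file=sys.stderr)
        kwargs["seed"] = seed
    if method == "forest":
        kwargs["verbose"] = verbose
    result = fn(matrix, **kwargs)
    result.method = method
    return result
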