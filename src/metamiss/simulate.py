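"""Synthetic metabolomics data and controlled amputation.

Complete ground-truth matrices are drawn from a low-rank log-normal model:
``X = exp(mu + s * (U V') / sqrt(r) + E)`` with iid Gaussian factors ``U, V``
and iid noise ``E``.  The low-rank log-scale structure mimics the correlated
blocks of co-regulated metabolites seen in real LC/GC-MS feature tables,
while the log-normal marginal reproduces their right-skewed intensity
distributions.

Amputation removes cells from a complete matrix under a controlled
mechanism, keeping ground truth:

* MCAR — each cell missing independently with fixed probability;
* MAR — missingness of every non-driver cell follows a logistic function of
  one fully observed driver metabolite, with the intercept calibrated so the
  overall missing fraction hits the requested target;
* MNAR-LOD — per-metabolite censoring below an empirical quantile threshold,
  either deterministic (everything below the limit of detection is lost) or
  probabilistic (a logistic dropout curve centred at the threshold);
* MIXTURE — a weighted combination; the total missing budget is split by
  weight and mechanisms are applied in the order MNAR-LOD, MAR, MCAR so that
  censoring acts on genuinely small values before random mechanisms consume
  the budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import IntensityMatrix
from .exceptions import ConfigError

MECHANISMS = ("MCAR", "MAR", "MNAR_LOD", "MIXTURE")

# steepness of the probabilistic LOD dropout curve, in units of column sd
_LOD_LOGISTIC_SCALE = 0.25


@dataclass
class SimulationConfig:
    """Shape and distributional parameters of a synthetic intensity matrix.

    ``mean_log_intensity`` / ``sd_log_intensity`` set the log-scale location
    and spread of the metabolite intensities; ``latent_rank`` controls how
    many shared latent factors induce correlation between metabolites and
    ``noise_sd`` is the iid log-scale measurement noise on top.
    """

    n_samples: int
    n_metabolites: int
    latent_rank: int = 3
    noise_sd: float = 0.3
    mean_log_intensity: float = 7.0
    sd_log_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_metabolites < 1:
            raise ConfigError("matrix dimensions must be positive")
        if self.latent_rank < 0 or self.latent_rank > min(self.n_samples, self.n_metabolites):
            raise ConfigError(
                f"latent_rank={self.latent_rank} must lie in "
                f"[0, min(n_samples, n_metabolites)={min(self.n_samples, self.n_metabolites)}]"
            )
        if self.noise_sd < 0 or self.sd_log_intensity <= 0:
            raise ConfigError("noise_sd must be >= 0 and sd_log_intensity > 0")


@dataclass
class AmputationPattern:
    """Specification of a missingness mechanism and its parameters."""

    mechanism: str
    missing_fraction: float = 0.2
    mar_driver: int | str = "auto"
    mar_strength: float = 2.0
    lod_quantile: float | None = None
    lod_mode: str = "deterministic"
    mixture_weights: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigError(f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigError("missing_fraction must lie in [0, 1]")
        if self.lod_mode not in ("deterministic", "probabilistic"):
            raise ConfigError("lod_mode must be 'deterministic' or 'probabilistic'")
        if self.mechanism == "MIXTURE":
            if not self.mixture_weights:
                raise ConfigError("MIXTURE pattern requires mixture_weights")
            w = self.mixture_weights
            unknown = set(w) - {"MCAR", "MAR", "MNAR_LOD"}
            if unknown:
                raise ConfigError(f"unknown mixture components: {sorted(unknown)}")
            if any(v < 0 for v in w.values()):
                raise ConfigError("mixture weights must be non-negative")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ConfigError(f"mixture weights must sum to 1, got {sum(w.values())}")
        elif self.mixture_weights is not None:
            raise ConfigError("mixture_weights only allowed with mechanism='MIXTURE'")
        if self.mechanism == "MNAR_LOD":
            q = self.lod_quantile if self.lod_quantile is not None else self.missing_fraction
            if not 0.0 < q < 1.0:
                raise ConfigError("lod_quantile must lie strictly in (0, 1)")

    def label(self) -> str:
        """Compact human-readable identifier used in scenario ids."""
        if self.mechanism == "MIXTURE":
            parts = "+".join(f"{k.lower()}{v:g}" for k, v in sorted(self.mixture_weights.items()))
            return f"mix[{parts}]_f{self.missing_fraction:g}"
        return f"{self.mechanism.lower()}_f{self.missing_fraction:g}"


@dataclass
class AmputationResult:
    """An amputed matrix together with its ground truth and mechanism labels."""

    amputed: IntensityMatrix
    truth: np.ndarray
    mechanism_per_cell: np.ndarray  # "" where observed, else mechanism name

    def __post_init__(self) -> None:
        obs = ~self.amputed.mask
        assert np.array_equal(self.amputed.values[obs], self.truth[obs])


@dataclass
class BenchmarkScenario:
    """One (shape, pattern) cell of a benchmark grid with its derived seed."""

    scenario_id: str
    config: SimulationConfig
    pattern: AmputationPattern
    seed: int


def generate_complete(config: SimulationConfig) -> IntensityMatrix:
    """Draw a complete (no missing cells) low-rank log-normal matrix."""
    rng = np.random.default_rng(config.seed)
    n, m, r = config.n_samples, config.n_metabolites, config.latent_rank
    if r > 0:
        u = rng.standard_normal((n, r))
        v = rng.standard_normal((m, r))
        signal = (u @ v.T) / np.sqrt(r)
    else:
        signal = np.zeros((n, m))
    log_x = config.mean_log_intensity + config.sd_log_intensity * signal
    if config.noise_sd > 0:
        log_x = log_x + config.noise_sd * rng.standard_normal((n, m))
    return IntensityMatrix(np.exp(log_x), np.zeros((n, m), dtype=bool))


def _as_result(truth: IntensityMatrix, mask: np.ndarray, labels: np.ndarray) -> AmputationResult:
    values = truth.values.copy()
    values[mask] = np.nan
    amputed = IntensityMatrix(values, mask, list(truth.sample_ids), list(truth.metabolite_ids))
    return AmputationResult(amputed=amputed, truth=truth.values.copy(), mechanism_per_cell=labels)


def _new_labels(shape) -> np.ndarray:
    return np.full(shape, "", dtype="<U8")


def ampute_mcar(truth: IntensityMatrix, missing_fraction: float, seed: int = 0) -> AmputationResult:
    """Mask each cell independently with probability ``missing_fraction``."""
    if not 0.0 <= missing_fraction <= 1.0:
        raise ConfigError("missing_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(truth.values.shape) < missing_fraction
    labels = _new_labels(truth.values.shape)
    labels[mask] = "MCAR"
    return _as_result(truth, mask, labels)


def _resolve_driver(values: np.ndarray, mar_driver: int | str) -> int:
    if mar_driver == "auto":
        # most variable metabolite on the log scale drives the missingness
        return int(np.argmax(np.var(np.log(np.maximum(values, 1e-300)), axis=0)))
    j = int(mar_driver)
    if not 0 <= j < values.shape[1]:
        raise ConfigError(f"mar_driver index {j} out of range for {values.shape[1]} metabolites")
    return j


def _mar_probabilities(
    values: np.ndarray, driver: int, strength: float, target_fraction: float
) -> np.ndarray:
    """Per-sample masking probability: logistic in the standardized driver,
    intercept calibrated by root finding so the mean probability over
    non-driver cells equals ``target_fraction``."""
    z = np.log(np.maximum(values[:, driver], 1e-300))
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)

    def mean_prob(intercept: float) -> float:
        return float(expit(intercept - strength * z).mean())

    if target_fraction <= 0:
        return np.zeros_like(z)
    if target_fraction >= 1:
        return np.ones_like(z)
    lo, hi = -60.0, 60.0
    intercept = brentq(lambda a: mean_prob(a) - target_fraction, lo, hi, xtol=1e-10)
    return expit(intercept - strength * z)


def ampute_mar(
    truth: IntensityMatrix,
    missing_fraction: float,
    mar_driver: int | str = "auto",
    mar_strength: float = 2.0,
    seed: int = 0,
) -> AmputationResult:
    """Missing-at-random amputation driven by one fully observed metabolite.

    Samples with low driver intensity lose more cells; the driver column
    itself is never masked, and the intercept of the logistic link is
    calibrated so the expected overall missing share equals
    ``missing_fraction``.
    """
    if mar_strength < 0:
        raise ConfigError("mar_strength must be >= 0")
    n, m = truth.values.shape
    if m < 2:
        raise ConfigError("MAR amputation needs at least 2 metabolites")
    driver = _resolve_driver(truth.values, mar_driver)
    # the driver column stays observed, so non-driver cells carry the budget
    target = missing_fraction * m / (m - 1)
    if target > 1.0:
        raise ConfigError("missing_fraction too high to be absorbed by non-driver columns")
    p = _mar_probabilities(truth.values, driver, mar_strength, target)
    rng = np.random.default_rng(seed)
    mask = rng.random((n, m)) < p[:, None]
    mask[:, driver] = False
    labels = _new_labels((n, m))
    labels[mask] = "MAR"
    return _as_result(truth, mask, labels)


def _lod_thresholds(values: np.ndarray, quantile: float) -> np.ndarray:
    return np.quantile(values, quantile, axis=0)


def ampute_mnar_lod(
    truth: IntensityMatrix,
    lod_quantile: float,
    lod_mode: str = "deterministic",
    seed: int = 0,
) -> AmputationResult:
    """Left-censor each metabolite below its empirical ``lod_quantile``.

    Deterministic mode loses exactly the cells below the per-column
    threshold; probabilistic mode applies a logistic dropout curve centred at
    the threshold, so masking concentrates below it without a hard cut.
    """
    if not 0.0 < lod_quantile < 1.0:
        raise ConfigError("lod_quantile must lie strictly in (0, 1)")
    vals = truth.values
    t = _lod_thresholds(vals, lod_quantile)
    if lod_mode == "deterministic":
        mask = vals < t[None, :]
    elif lod_mode == "probabilistic":
        sd = vals.std(axis=0)
        const = sd <= 0
        if const.any():
            warnings.warn(
                "constant column(s) in probabilistic LOD mode; falling back to "
                "deterministic thresholding for them",
                stacklevel=2,
            )
        scale = np.where(const, 1.0, _LOD_LOGISTIC_SCALE * np.where(sd > 0, sd, 1.0))
        p = expit((t[None, :] - vals) / scale[None, :])
        rng = np.random.default_rng(seed)
        mask = rng.random(vals.shape) < p
        if const.any():
            mask[:, const] = vals[:, const] < t[None, const]
    else:
        raise ConfigError("lod_mode must be 'deterministic' or 'probabilistic'")
    labels = _new_labels(vals.shape)
    labels[mask] = "MNAR_LOD"
    return _as_result(truth, mask, labels)


def _split_budget(total: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` cells across mechanisms."""
    keys = [k for k in ("MNAR_LOD", "MAR", "MCAR") if weights.get(k, 0.0) > 0]
    raw = {k: total * weights[k] for k in keys}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(out.values())
    for k in sorted(keys, key=lambda k: raw[k] - out[k], reverse=True)[:short]:
        out[k] += 1
    return out


def ampute_mixture(truth: IntensityMatrix, pattern: AmputationPattern) -> AmputationResult:
    """Apply a weighted mixture of mechanisms with an exact total budget.

    The total missing budget ``missing_fraction * n_cells`` is apportioned
    across mechanisms by weight; mechanisms run in the order
    MNAR-LOD -> MAR -> MCAR, each masking only still-observed cells.
    """
    if pattern.mechanism != "MIXTURE":
        raise ConfigError("ampute_mixture requires a MIXTURE pattern")
    vals = truth.values
    n, m = vals.shape
    rng = np.random.default_rng(pattern.seed)
    total = int(round(pattern.missing_fraction * n * m))
    budgets = _split_budget(total, pattern.mixture_weights)
    mask = np.zeros((n, m), dtype=bool)
    labels = _new_labels((n, m))

    b = budgets.get("MNAR_LOD", 0)
    if b > 0:
        # spread the censoring budget over columns; the effective LOD quantile
        # per column is b / n_cells
        per_col = np.full(m, b // m)
        extra = rng.choice(m, size=b - int(per_col.sum()), replace=False)
        per_col[extra] += 1
        order = np.argsort(vals, axis=0, kind="stable")
        for j in range(m):
            k = int(per_col[j])
            if k > 0:
                rows = order[:k, j]
                mask[rows, j] = True
                labels[rows, j] = "MNAR_LOD"

    b = budgets.get("MAR", 0)
    if b > 0:
        driver = _resolve_driver(vals, pattern.mar_driver)
        cand = ~mask
        cand[:, driver] = False
        idx = np.nonzero(cand)
        if b > idx[0].size:
            raise ConfigError("MAR budget exceeds available non-driver cells")
        p_row = _mar_probabilities(vals, driver, pattern.mar_strength, b / max(idx[0].size, 1))
        w = p_row[idx[0]]
        w = w / w.sum() if w.sum() > 0 else np.full(idx[0].size, 1.0 / idx[0].size)
        chosen = rng.choice(idx[0].size, size=b, replace=False, p=w)
        mask[idx[0][chosen], idx[1][chosen]] = True
        labels[idx[0][chosen], idx[1][chosen]] = "MAR"

    b = budgets.get("MCAR", 0)
    if b > 0:
        idx = np.nonzero(~mask)
        if b > idx[0].size:
            raise ConfigError("MCAR budget exceeds remaining cells")
        chosen = rng.choice(idx[0].size, size=b, replace=False)
        mask[idx[0][chosen], idx[1][chosen]] = True
        labels[idx[0][chosen], idx[1][chosen]] = "MCAR"

    return _as_result(truth, mask, labels)


def ampute(truth: IntensityMatrix, pattern: AmputationPattern) -> AmputationResult:
    """Dispatch to the amputation routine matching ``pattern.mechanism``."""
    if pattern.mechanism == "MCAR":
        return ampute_mcar(truth, pattern.missing_fraction, seed=pattern.seed)
    if pattern.mechanism == "MAR":
        return ampute_mar(
            truth,
            pattern.missing_fraction,
            mar_driver=pattern.mar_driver,
            mar_strength=pattern.mar_strength,
            seed=pattern.seed,
        )
    if pattern.mechanism == "MNAR_LOD":
        q = pattern.lod_quantile if pattern.lod_quantile is not None else pattern.missing_fraction
        return ampute_mnar_lod(truth, q, lod_mode=pattern.lod_mode, seed=pattern.seed)
    return ampute_mixture(truth, pattern)


def default_patterns() -> list[AmputationPattern]:
    """The shipped 10-pattern grid: three fractions x three single mechanisms,
    plus one equal-weight mixture."""
    patterns = []
    for frac in (0.1, 0.2, 0.3):
        patterns.append(AmputationPattern("MCAR", missing_fraction=frac))
        patterns.append(AmputationPattern("MAR", missing_fraction=frac))
        patterns.append(AmputationPattern("MNAR_LOD", missing_fraction=frac, lod_quantile=frac))
    patterns.append(
        AmputationPattern(
            "MIXTURE",
            missing_fraction=0.2,
            mixture_weights={"MCAR": 1 / 3, "MAR": 1 / 3, "MNAR_LOD": 1 / 3},
        )
    )
    return patterns


#: 23 shipped dataset shapes (n_samples, n_metabolites), 20-500 x 10-200.
DEFAULT_SHAPES: tuple[tuple[int, int], ...] = (
    (20, 10), (20, 25), (20, 50), (20, 100),
    (50, 10), (50, 25), (50, 50), (50, 100), (50, 200),
    (100, 10), (100, 25), (100, 50), (100, 100), (100, 200),
    (200, 10), (200, 25), (200, 50), (200, 100), (200, 200),
    (500, 10), (500, 25), (500, 50), (500, 100),
)


def default_shapes() -> list[SimulationConfig]:
    return [SimulationConfig(n_samples=n, n_metabolites=m) for n, m in DEFAULT_SHAPES]


def _derived_seed(grid_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=grid_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def benchmark_grid(
    patterns: list[AmputationPattern] | None = None,
    shapes: list[SimulationConfig] | None = None,
    grid_seed: int = 0,
) -> list[BenchmarkScenario]:
    """Cross every pattern with every shape; each scenario carries a
    reproducible seed derived from ``grid_seed`` and its grid position."""
    if patterns is None:
        patterns = default_patterns()
    if shapes is None:
        shapes = default_shapes()
    if not patterns or not shapes:
        raise ConfigError("patterns and shapes must be non-empty")
    scenarios = []
    i = 0
    for pi, pattern in enumerate(patterns):
        for si, shape in enumerate(shapes):
            seed = _derived_seed(grid_seed, i)
            scenarios.append(
                BenchmarkScenario(
                    scenario_id=f"p{pi:02d}_{pattern.label()}__s{si:02d}_"
                    f"{shape.n_samples}x{shape.n_metabolites}",
                    config=replace(shape, seed=seed),
                    pattern=replace(pattern, seed=_derived_seed(grid_seed, i + 10_000_000)),
                    seed=seed,
                )
            )
            i += 1
    return scenarios
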