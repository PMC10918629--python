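"""NRMSE scoring and the benchmark harness.

The accuracy measure is the normalized root mean squared error over the
amputed cells, with per-metabolite variance normalization:

    NRMSE = sqrt( mean over masked (i,j) of (completed_ij - truth_ij)^2 / Var_j )

where ``Var_j`` is the sample variance (n - 1 denominator, the R ``var``
convention) of metabolite j's true values.  Normalizing per variable rather
than globally makes the score insensitive to heteroscedasticity between
metabolites: a 10% error on a high-abundance metabolite and a 10% error on
a trace metabolite weigh the same.

The harness runs each method on each scenario in a separate process under a
wall-clock budget (default 120 s), retrying up to three times; a method that
fails every attempt is "not working" for that scenario.  Failures (errors or
timeouts) are recorded as results, never propagated, so one unstable method
cannot abort a benchmark.
"""

from __future__ import annotations

import multiprocessing
import time
import traceback
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import IntensityMatrix
from .exceptions import ConfigError, EvaluationError, UnknownMethodError
from .impute import _REGISTRY, impute
from .simulate import BenchmarkScenario, ampute, generate_complete

DEFAULT_TIMEOUT_S = 120.0
DEFAULT_ATTEMPTS = 3


@dataclass
class NRMSEValue:
    value: float
    n_cells: int


@dataclass
class BenchmarkResult:
    """Outcome of one attempt of one method on one scenario."""

    method: str
    scenario_id: str
    attempt: int
    status: str  # ok | error | timeout
    nrmse: float | None
    wall_time_s: float
    error_message: str | None = None


@dataclass
class MethodPerformance:
    """Per-method aggregate over a benchmark grid."""

    method: str
    mean_nrmse: float | None
    max_time_s: float
    success_rate: float
    per_mechanism_nrmse: dict[str, float] = field(default_factory=dict)
    timeout_failure_share: float = 0.0
    error_failure_share: float = 0.0


def nrmse(truth: np.ndarray, completed: np.ndarray, mask: np.ndarray) -> NRMSEValue:
    """Per-variable-normalized RMSE over the masked cells (see module docs)."""
    truth = np.asarray(truth, dtype=float)
    completed = np.asarray(completed, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if truth.shape != completed.shape or truth.shape != mask.shape:
        raise EvaluationError("truth, completed and mask shapes must agree")
    if not mask.any():
        raise EvaluationError("mask selects no cells to score")
    if truth.shape[0] < 2:
        raise EvaluationError("NRMSE needs at least 2 samples to estimate column variances")
    var = truth.var(axis=0, ddof=1)
    scored_cols = np.nonzero(mask.any(axis=0))[0]
    zero_var = scored_cols[var[scored_cols] <= 0]
    if zero_var.size:
        raise EvaluationError(
            f"zero-variance column(s) {zero_var.tolist()} cannot be scored"
        )
    i, j = np.nonzero(mask)
    sq = (completed[i, j] - truth[i, j]) ** 2 / var[j]
    return NRMSEValue(value=float(np.sqrt(sq.mean())), n_cells=int(mask.sum()))


# --------------------------------------------------------------------------
# timeout-isolated execution

_FORK = multiprocessing.get_context("fork")


def _child_imputation(conn, matrix: IntensityMatrix, method: str, params, seed) -> None:
    try:
        res = impute(matrix, method, params=params, verbose=False, seed=seed)
        conn.send(("ok", res.completed))
    except BaseException as exc:  # report, never raise across the pipe
        conn.send(("error", f"{type(exc).__name__}: {exc}\n{traceback.format_exc(limit=3)}"))
    finally:
        conn.close()


def _run_with_timeout(matrix, method, params, seed, timeout_s):
    """Run one imputation in a terminatable child process.

    Returns (status, payload, wall_time): payload is the completed matrix on
    "ok", an error message on "error", None on "timeout".
    """
    parent_conn, child_conn = _FORK.Pipe(duplex=False)
    proc = _FORK.Process(
        target=_child_imputation, args=(child_conn, matrix, method, params, seed)
    )
    t0 = time.perf_counter()
    proc.start()
    child_conn.close()
    payload = None
    status = "timeout"
    if parent_conn.poll(timeout_s):
        try:
            status, payload = parent_conn.recv()
        except EOFError:
            status, payload = "error", "worker process died without reporting a result"
    wall = time.perf_counter() - t0
    if proc.is_alive():
        proc.terminate()
    proc.join()
    parent_conn.close()
    return status, payload, wall


def _scenario_data(scenario: BenchmarkScenario):
    truth = generate_complete(scenario.config)
    return truth, ampute(truth, scenario.pattern)


def run_scenario(
    method: str,
    scenario: BenchmarkScenario,
    timeout_s: float = DEFAULT_TIMEOUT_S,
    attempts: int = DEFAULT_ATTEMPTS,
    method_params: dict | None = None,
) -> list[BenchmarkResult]:
    """Run one method on one scenario, retrying failures up to ``attempts``
    times; each attempt runs in an isolated, terminatable process."""
    if method not in _REGISTRY:
        raise UnknownMethodError(f"unknown method {method!r}")
    if timeout_s <= 0 or attempts < 1:
        raise ConfigError("timeout_s must be > 0 and attempts >= 1")
    truth, amp = _scenario_data(scenario)
    results = []
    for attempt in range(1, attempts + 1):
        seed = (scenario.seed * 1000 + attempt) % (2**31)
        status, payload, wall = _run_with_timeout(
            amp.amputed, method, method_params, seed, timeout_s
        )
        if status == "ok":
            score = nrmse(truth.values, payload, amp.amputed.mask)
            results.append(
                BenchmarkResult(method, scenario.scenario_id, attempt, "ok", score.value, wall)
            )
            break
        results.append(
            BenchmarkResult(
                method,
                scenario.scenario_id,
                attempt,
                status,
                None,
                wall,
                error_message=payload if status == "error" else f"timeout after {timeout_s:g}s",
            )
        )
    return results


def run_benchmark(
    methods: list[str],
    grid: list[BenchmarkScenario],
    timeout_s: float = DEFAULT_TIMEOUT_S,
    attempts: int = DEFAULT_ATTEMPTS,
    n_jobs: int = 1,
) -> list[BenchmarkResult]:
    """Run every method on every scenario.

    Execution order (and serial vs ``n_jobs``-parallel) does not affect the
    result set: each (method, scenario) pair is seeded independently.
    """
    if not methods or not grid:
        raise ConfigError("methods and grid must be non-empty")
    unknown = [m for m in methods if m not in _REGISTRY]
    if unknown:
        raise UnknownMethodError(f"unknown method(s): {unknown}")
    tasks = [(m, sc) for m in methods for sc in grid]
    if n_jobs == 1:
        nested = [run_scenario(m, sc, timeout_s, attempts) for m, sc in tasks]
    else:
        from joblib import Parallel, delayed

        nested = Parallel(n_jobs=n_jobs)(
            delayed(run_scenario)(m, sc, timeout_s, attempts) for m, sc in tasks
        )
    results = [r for group in nested for r in group]
    results.sort(key=lambda r: (r.method, r.scenario_id, r.attempt))
    return results


def results_to_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Tidy results table: one row per method x scenario x attempt."""
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "scenario_id": r.scenario_id,
                "attempt": r.attempt,
                "status": r.status,
                "nrmse": r.nrmse,
                "wall_time_s": r.wall_time_s,
                "error_message": r.error_message,
            }
            for r in results
        ]
    )


def summarize(
    results: list[BenchmarkResult], grid: list[BenchmarkScenario]
) -> list[MethodPerformance]:
    """Aggregate per method: success rate, mean and per-mechanism NRMSE over
    ok scenarios, max wall time, and the failure-cause split."""
    mechanism_of = {sc.scenario_id: sc.pattern.mechanism for sc in grid}
    by_method: dict[str, list[BenchmarkResult]] = {}
    for r in results:
        by_method.setdefault(r.method, []).append(r)
    out = []
    for method in sorted(by_method):
        rs = by_method[method]
        scenario_ids = sorted({r.scenario_id for r in rs})
        ok_first: dict[str, BenchmarkResult] = {}
        for r in sorted(rs, key=lambda r: r.attempt):
            if r.status == "ok" and r.scenario_id not in ok_first:
                ok_first[r.scenario_id] = r
        n_ok = len(ok_first)
        failures = [r for r in rs if r.status != "ok"]
        n_fail = len(failures)
        n_timeout = sum(r.status == "timeout" for r in failures)
        per_mech: dict[str, list[float]] = {}
        for sid, r in ok_first.items():
            per_mech.setdefault(mechanism_of.get(sid, "UNKNOWN"), []).append(r.nrmse)
        out.append(
            MethodPerformance(
                method=method,
                mean_nrmse=(
                    float(np.mean([r.nrmse for r in ok_first.values()])) if ok_first else None
                ),
                max_time_s=float(max(r.wall_time_s for r in rs)),
                success_rate=n_ok / len(scenario_ids),
                per_mechanism_nrmse={k: float(np.mean(v)) for k, v in sorted(per_mech.items())},
                timeout_failure_share=(n_timeout / n_fail) if n_fail else 0.0,
                error_failure_share=((n_fail - n_timeout) / n_fail) if n_fail else 0.0,
            )
        )
    return out


def performance_to_frame(performance: list[MethodPerformance]) -> pd.DataFrame:
    rows = []
    for p in performance:
        row = {
            "method": p.method,
            "mean_nrmse": p.mean_nrmse,
            "max_time_s": p.max_time_s,
            "success_rate": p.success_rate,
            "timeout_failure_share": p.timeout_failure_share,
            "error_failure_share": p.error_failure_share,
        }
        for mech, v in p.per_mechanism_nrmse.items():
            row[f"nrmse_{mech.lower()}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def rank_methods(
    performance: list[MethodPerformance],
    criterion: str = "accuracy",
    mechanism: str = "overall",
    success_floor: float = 0.8,
) -> list[str]:
    """Order methods by accuracy (ascending NRMSE, overall or per mechanism)
    or speed (ascending max wall time).  Methods whose success rate falls
    below ``success_floor`` are demoted below all others; ties break
    alphabetically."""
    if criterion not in ("accuracy", "speed"):
        raise ConfigError("criterion must be 'accuracy' or 'speed'")
    valid_mechs = {"overall", "MCAR", "MAR", "MNAR_LOD", "MIXTURE"}
    if mechanism not in valid_mechs:
        raise ConfigError(f"mechanism must be one of {sorted(valid_mechs)}")
    if not performance:
        raise ConfigError("performance list must be non-empty")

    def score(p: MethodPerformance) -> float:
        if criterion == "speed":
            return p.max_time_s
        if mechanism == "overall":
            return p.mean_nrmse if p.mean_nrmse is not None else np.inf
        return p.per_mechanism_nrmse.get(mechanism, np.inf)

    return [
        p.method
        for p in sorted(
            performance, key=lambda p: (p.success_rate < success_floor, score(p), p.method)
        )
    ]
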