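"""Synthetic benchmark scenarios and selection/estimation metrics.

Three logistic partly linear scenarios share one generator skeleton and
differ only in the nonzero values of the high-dimensional coefficient
vector:

* scenario "1"  (strong signals):       beta0 nonzeros (1, -1, -1, 0.75, 0.75)
* scenario "2"  (strong + weak):        beta0 nonzeros (1, -0.5, -1, 0.4, 0.75)
* scenario "3"  (high dimension, p>n):  beta0 nonzeros (2, -2, -2, 1.5, 1.5)
* scenario "3-weak": scenario 3 design with scenario 2's nonzeros

The nonzeros sit at coordinates (1, 2, p-2, p-1, p) in 1-based terms.  The
high-dimensional block is drawn from a mean-zero Gaussian with AR(1)
correlation rho = 0.25; five Bernoulli(0.5) indicator covariates carry
alpha0 = (1, -0.5, -0.5, 0.75, -1); four continuous covariates enter through
smooth functions that all vanish at their domain midpoints:

    psi1(z) = 0.1 (z - 3)^2          on (1, 5)
    psi2(z) = 0.2 (cos(2 pi z) + 1)  on (0, 1)
    psi3(z) = 0.2 sin(2 pi z)        on (0, 1)
    psi4(z) = 0.2 (z + 1)^3          on (-3, 1)

Per-replication quality is summarized by the quadratic-form error
``(beta_hat - beta0)' Sigma_X (beta_hat - beta0)`` and the usual selection
counts (TP, FP, FN, model size, misclassification, exact-support indicator).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .basis import SieveBasisSpec
from .core import (BARConfig, FitError, GPLMDataset, fit_gplm_bar,
                   fit_unpenalized)

__all__ = [
    "ScenarioTruth",
    "SelectionMetrics",
    "true_psi",
    "gen_scenario",
    "compute_metrics",
    "run_study",
    "SCENARIOS",
]

RHO = 0.25
ALPHA0 = np.array([1.0, -0.5, -0.5, 0.75, -1.0])
Z_RANGES = ((1.0, 5.0), (0.0, 1.0), (0.0, 1.0), (-3.0, 1.0))
_NONZEROS = {
    "1": np.array([1.0, -1.0, -1.0, 0.75, 0.75]),
    "2": np.array([1.0, -0.5, -1.0, 0.4, 0.75]),
    "3": np.array([2.0, -2.0, -2.0, 1.5, 1.5]),
    "3-weak": np.array([1.0, -0.5, -1.0, 0.4, 0.75]),
}
SCENARIOS = tuple(_NONZEROS)


def true_psi(j: int, z):
    """True smooth effect of continuous covariate ``j`` (1-based)."""
    z = np.asarray(z, dtype=float)
    if j == 1:
        return 0.1 * (z - 3.0) ** 2
    if j == 2:
        return 0.2 * (np.cos(2.0 * np.pi * z) + 1.0)
    if j == 3:
        return 0.2 * np.sin(2.0 * np.pi * z)
    if j == 4:
        return 0.2 * (z + 1.0) ** 3
    raise ValueError(f"j must be in 1..4, got {j}")


@dataclasses.dataclass(frozen=True)
class ScenarioTruth:
    """True parameters behind a generated dataset."""

    beta0: np.ndarray
    alpha0: np.ndarray
    rho: float
    support: np.ndarray
    z_ranges: tuple
    family: str = "logistic"

    @property
    def p(self) -> int:
        return self.beta0.shape[0]

    @property
    def q(self) -> int:
        return self.support.shape[0]

    def quadratic_form(self, v: np.ndarray) -> float:
        """``v' Sigma_X v`` under the AR(1) covariance, exploiting sparsity."""
        v = np.asarray(v, dtype=float)
        idx = np.flatnonzero(v)
        if idx.size == 0:
            return 0.0
        sub = self.rho ** np.abs(idx[:, None] - idx[None, :])
        return float(v[idx] @ sub @ v[idx])


def _support_indices(p: int) -> np.ndarray:
    if p < 6:
        raise ValueError("p must be at least 6 to place the 5 nonzero signals")
    return np.array([0, 1, p - 3, p - 2, p - 1])


def scenario_truth(scenario: str, p: int, family: str = "logistic") -> ScenarioTruth:
    key = str(scenario)
    if key not in _NONZEROS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    support = _support_indices(p)
    beta0 = np.zeros(p)
    beta0[support] = _NONZEROS[key]
    return ScenarioTruth(beta0=beta0, alpha0=ALPHA0.copy(), rho=RHO,
                         support=support, z_ranges=Z_RANGES, family=family)


def gen_scenario(scenario: str, n: int, p: int, seed,
                 family: str = "logistic"):
    """Generate one replication of a benchmark scenario.

    Returns ``(GPLMDataset, ScenarioTruth)``.  Deterministic given the seed:
    the same seed always yields bit-identical data.
    """
    if n < 1 or p < 6:
        raise ValueError("need n >= 1 and p >= 6")
    truth = scenario_truth(scenario, p, family=family)
    rng = np.random.default_rng(seed)

    # AR(1) Gaussian columns: x_1 ~ N(0,1), x_j = rho x_{j-1} + sqrt(1-rho^2) e_j
    E = rng.standard_normal((n, p))
    X = np.empty((n, p))
    X[:, 0] = E[:, 0]
    fac = np.sqrt(1.0 - truth.rho ** 2)
    for j in range(1, p):
        X[:, j] = truth.rho * X[:, j - 1] + fac * E[:, j]

    W = rng.binomial(1, 0.5, size=(n, ALPHA0.shape[0])).astype(float)
    Z = np.column_stack([rng.uniform(lo, hi, size=n) for lo, hi in Z_RANGES])

    eta = X @ truth.beta0 + W @ truth.alpha0
    for j in range(1, 5):
        eta += true_psi(j, Z[:, j - 1])

    if family == "logistic":
        y = rng.binomial(1, expit(eta)).astype(float)
    elif family == "poisson":
        y = rng.poisson(np.exp(np.minimum(eta, 30.0))).astype(float)
    else:
        raise ValueError(f"unknown family {family!r}")

    data = GPLMDataset.from_arrays(y, X, W, Z, family=family)
    return data, truth


@dataclasses.dataclass(frozen=True)
class SelectionMetrics:
    """Per-replication evaluation record."""

    mse: float
    tp: int
    fp: int
    fn: int
    tm: int

    @property
    def ms(self) -> int:
        return self.tp + self.fp

    @property
    def mc(self) -> int:
        return self.fn + self.fp


def compute_metrics(beta_hat: np.ndarray, truth: ScenarioTruth) -> SelectionMetrics:
    """Selection counts and the quadratic-form error against the truth."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_hat.shape != truth.beta0.shape:
        raise ValueError(f"beta_hat must have length {truth.p}")
    selected = np.flatnonzero(beta_hat != 0.0)
    support = set(truth.support.tolist())
    sel = set(selected.tolist())
    tp = len(sel & support)
    fp = len(sel - support)
    fn = len(support - sel)
    tm = int(sel == support)
    mse = truth.quadratic_form(beta_hat - truth.beta0)
    return SelectionMetrics(mse=mse, tp=tp, fp=fp, fn=fn, tm=tm)


# ---------------------------------------------------------------------------
# replicated studies
# ---------------------------------------------------------------------------

def _method_config(method, base: BARConfig | None) -> BARConfig:
    base = base or BARConfig()
    kwargs = dataclasses.asdict(base)
    if method == "bar_aic":
        kwargs.update(lambda_rule="aic", lambda_value=None)
    elif method == "bar_bic":
        kwargs.update(lambda_rule="bic", lambda_value=None)
    elif method == "bar_hbic":
        kwargs.update(lambda_rule="hbic", lambda_value=None)
    elif method.startswith("bar_fixed:"):
        kwargs.update(lambda_rule="fixed", lambda_value=float(method.split(":", 1)[1]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return BARConfig(**kwargs)


def _run_replication(scenario, n, p, seed, methods, base_config, family):
    data, truth = gen_scenario(scenario, n, p, seed, family=family)
    spec = SieveBasisSpec.from_data(data.Z, degree=(base_config or BARConfig()).degree)
    out = {}
    for method in methods:
        try:
            if method == "oracle":
                fit = fit_unpenalized(data, spec=spec, support=truth.support,
                                      config=base_config)
            else:
                fit = fit_gplm_bar(data, spec=spec,
                                   config=_method_config(method, base_config))
            out[method] = compute_metrics(fit.coefficients.beta, truth)
        except FitError as exc:
            out[method] = None
            out.setdefault("_errors", []).append((method, str(exc)))
    return out


def run_study(scenario: str, n: int, p: int, reps: int,
              methods: Sequence[str] = ("bar_bic",), base_seed: int = 0,
              n_jobs: int = 1, config: BARConfig | None = None,
              family: str = "logistic") -> pd.DataFrame:
    """Replicated benchmark: one aggregate row per method.

    Replication ``r`` uses seed ``base_seed + r``, so any single row of the
    study can be re-run in isolation.  Methods are fit on the same generated
    data within each replication.  Columns: ``method, MMSE, MMSE_SD, TP, FP,
    MS, MC, TM_pct, n_reps, n_failed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    methods = list(methods)
    seeds = [base_seed + r for r in range(reps)]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        records = Parallel(n_jobs=n_jobs)(
            delayed(_run_replication)(scenario, n, p, s, methods, config, family)
            for s in seeds)
    else:
        records = [_run_replication(scenario, n, p, s, methods, config, family)
                   for s in seeds]

    rows = []
    for method in methods:
        mets = [rec[method] for rec in records if rec[method] is not None]
        n_failed = reps - len(mets)
        if not mets:
            rows.append({"method": method, "MMSE": np.nan, "MMSE_SD": np.nan,
                         "TP": np.nan, "FP": np.nan, "MS": np.nan, "MC": np.nan,
                         "TM_pct": np.nan, "n_reps": 0, "n_failed": n_failed})
            continue
        mses = np.array([m.mse for m in mets])
        rows.append({
            "method": method,
            "MMSE": float(np.median(mses)),
            "MMSE_SD": float(mses.std(ddof=1)) if len(mses) > 1 else 0.0,
            "TP": float(np.mean([m.tp for m in mets])),
            "FP": float(np.mean([m.fp for m in mets])),
            "MS": float(np.mean([m.ms for m in mets])),
            "MC": float(np.mean([m.mc for m in mets])),
            "TM_pct": 100.0 * float(np.mean([m.tm for m in mets])),
            "n_reps": len(mets),
            "n_failed": n_failed,
        })
    return pd.DataFrame(rows)
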