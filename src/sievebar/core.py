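"""Partly linear GLM likelihood, broken-adaptive-ridge fitting and inference.

The model links the mean of a binary (logistic) or count (Poisson) response
to a linear predictor

    eta_i = intercept + beta' x_i + alpha' w_i + sum_j psi_j(z_ij),

where ``x`` is the high-dimensional block (penalized; selection happens
here), ``w`` a small block of indicator covariates and the ``psi_j`` are
smooth functions of continuous covariates represented in a centered
Bernstein sieve (see :mod:`sievebar.basis`).

Selection and estimation run in one loop: a ridge-initialized estimate is
refined by iteratively reweighted ridge fits in which each coordinate's
penalty weight is ``lambda_n / beta_j_prev**2``; coordinates falling below a
drop threshold are fixed at exactly zero and removed permanently.  The
iteration limit of this scheme approximates best-subset (L0) selection while
every step stays a smooth convex problem.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from . import _solvers
from ._solvers import FitError
from .basis import SieveBasisSpec, SieveDesign, build_sieve_design

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "GPLMDataset",
    "GPLMCoefficients",
    "BARConfig",
    "FitResult",
    "BootstrapResult",
    "FitError",
    "sieve_loglik",
    "choose_lambda",
    "ridge_init",
    "bar_step",
    "fit_gplm_bar",
    "fit_unpenalized",
    "predict",
    "bootstrap_se",
]

FAMILIES = ("logistic", "poisson")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GPLMDataset:
    """Aligned observations ``(y, X, W, Z)`` with a family tag.

    ``X`` is stored standardized (mean zero, unit second moment with the
    ``n``-denominator convention); the original column centers/scales are
    kept for back-transformation and prediction.
    """

    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    Z: np.ndarray
    family: str = "logistic"
    x_center: np.ndarray = None
    x_scale: np.ndarray = None

    @classmethod
    def from_arrays(cls, y, X, W=None, Z=None, family="logistic",
                    standardize=True) -> "GPLMDataset":
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = y.shape[0]
        if X.shape[0] != n:
            raise ValueError(f"X has {X.shape[0]} rows, y has {n}")
        W = np.empty((n, 0)) if W is None else np.atleast_2d(np.asarray(W, dtype=float))
        Z = np.empty((n, 0)) if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.ndim == 2 and Z.shape[0] == 1 and n != 1:
            Z = Z.T
        if W.shape[0] != n or Z.shape[0] != n:
            raise ValueError("row counts of y, X, W, Z must agree")
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
        if family == "logistic":
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise ValueError("family mismatch: logistic response must be 0/1")
        else:
            if np.any(y < 0) or np.any(y != np.round(y)):
                raise ValueError(
                    "family mismatch: poisson response must be nonnegative integers"
                )
        if standardize:
            center = X.mean(axis=0)
            scale = np.sqrt(np.mean((X - center) ** 2, axis=0))
            if np.any(scale <= 0):
                bad = int(np.flatnonzero(scale <= 0)[0])
                raise ValueError(f"X column {bad} is constant; cannot standardize")
            X = (X - center) / scale
        else:
            center = np.zeros(X.shape[1])
            scale = np.ones(X.shape[1])
        return cls(y=y, X=X, W=W, Z=Z, family=family,
                   x_center=center, x_scale=scale)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def qw(self) -> int:
        return self.W.shape[1]

    @property
    def qz(self) -> int:
        return self.Z.shape[1]


@dataclasses.dataclass(frozen=True)
class GPLMCoefficients:
    """Partitioned coefficient vector ``(beta, alpha, gamma, intercept)``."""

    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    intercept: float = 0.0

    def linear_predictor(self, data: GPLMDataset, design: SieveDesign | None) -> np.ndarray:
        eta = np.full(data.n, self.intercept, dtype=float)
        if data.p:
            eta += data.X @ self.beta
        if data.qw:
            eta += data.W @ self.alpha
        if design is not None and design.n_columns:
            eta += design.matrix @ self.gamma
        return eta


@dataclasses.dataclass
class BARConfig:
    """Tuning and convergence settings for the iteratively reweighted fit.

    ``xi_n`` penalizes the high-dimensional block in the ridge
    initialization; its exact value is inconsequential for selection as long
    as it is not large.  ``lambda_rule`` picks the reweighting strength:
    ``aic`` (2), ``bic`` (log n), ``hbic`` (log(log n) * log p) or ``fixed``
    with an explicit ``lambda_value``.
    """

    xi_n: float = 1.0
    lambda_rule: str = "bic"
    lambda_value: float = None
    eps_outer: float = 1e-6
    max_outer: int = 500
    drop_threshold: float = 1e-6
    inner_tol: float = 1e-9
    max_inner: int = 200
    eps_stab: float = 1e-8
    stabilize: bool = True
    solver: str = "auto"          # auto | newton | woodbury | cd
    large_p_threshold: int = 1000
    degree: int = 3

    def __post_init__(self):
        if self.xi_n <= 0:
            raise ValueError("xi_n must be positive")
        if self.drop_threshold <= 0 or self.eps_outer <= 0:
            raise ValueError("drop_threshold and eps_outer must be positive")


@dataclasses.dataclass
class FitResult:
    """Converged estimate with its active set and fitting metadata."""

    coefficients: GPLMCoefficients
    active_set: np.ndarray
    n_outer: int
    converged: bool
    objective: float
    loglik: float
    spec: SieveBasisSpec
    lambda_n: float
    xi_n: float
    family: str
    x_center: np.ndarray
    x_scale: np.ndarray

    def coefficients_raw_scale(self) -> GPLMCoefficients:
        """Back-transform ``beta`` (and the intercept) to the raw X scale."""
        beta_raw = self.coefficients.beta / self.x_scale
        icept = self.coefficients.intercept - float(beta_raw @ self.x_center)
        return GPLMCoefficients(beta=beta_raw, alpha=self.coefficients.alpha,
                                gamma=self.coefficients.gamma, intercept=icept)


@dataclasses.dataclass
class BootstrapResult:
    """Resampling standard errors; failed refits are excluded and counted."""

    se_beta: np.ndarray           # over the full-fit active set
    active_set: np.ndarray
    se_alpha: np.ndarray
    se_gamma: np.ndarray
    se_intercept: float
    n_resamples: int
    n_failed: int


# ---------------------------------------------------------------------------
# likelihood and tuning
# ---------------------------------------------------------------------------

def sieve_loglik(data: GPLMDataset, coef: GPLMCoefficients,
                 design: SieveDesign | None = None) -> float:
    """Log-likelihood of the partly linear model at ``coef``.

    For the logistic family this is ``sum_i [y_i eta_i - log(1 + e^eta_i)]``
    and for Poisson ``sum_i [y_i eta_i - e^eta_i - log(y_i!)]``.
    """
    if data.p and coef.beta.shape != (data.p,):
        raise ValueError(f"beta must have length {data.p}")
    if data.qw and coef.alpha.shape != (data.qw,):
        raise ValueError(f"alpha must have length {data.qw}")
    if design is not None and coef.gamma.shape != (design.n_columns,):
        raise ValueError(f"gamma must have length {design.n_columns}")
    eta = coef.linear_predictor(data, design)
    return _solvers.loglik(data.y, eta, data.family)


def choose_lambda(rule: str, n: int = None, p: int = None,
                  value: float = None) -> float:
    """Tuning-parameter presets: AIC -> 2, BIC -> log n, HBIC -> log(log n) log p."""
    rule = str(rule).lower()
    if rule == "aic":
        return 2.0
    if rule == "bic":
        if n is None or n < 2:
            raise ValueError("BIC rule requires n >= 2")
        return math.log(n)
    if rule == "hbic":
        if n is None or n <= math.e:
            raise ValueError("HBIC rule requires n > e so that log(log n) > 0")
        if p is None or p < 1:
            raise ValueError("HBIC rule requires p >= 1")
        return math.log(math.log(n)) * math.log(p)
    if rule == "fixed":
        if value is None or value < 0:
            raise ValueError("fixed rule requires a nonnegative lambda_value")
        return float(value)
    raise ValueError(f"unknown lambda rule {rule!r}")


# ---------------------------------------------------------------------------
# weighted solves
# ---------------------------------------------------------------------------

def _assemble(data: GPLMDataset, design: SieveDesign | None, active) -> np.ndarray:
    nb = design.n_columns if design is not None else 0
    parts = []
    if len(active):
        parts.append(data.X[:, active])
    if data.qw:
        parts.append(data.W)
    if nb:
        parts.append(design.matrix)
    parts.append(np.ones((data.n, 1)))
    return np.hstack(parts)


def _unpack(theta, data: GPLMDataset, design: SieveDesign | None, active) -> GPLMCoefficients:
    nb = design.n_columns if design is not None else 0
    k = len(active)
    beta = np.zeros(data.p)
    if k:
        beta[active] = theta[:k]
    alpha = theta[k:k + data.qw].copy()
    gamma = theta[k + data.qw:k + data.qw + nb].copy()
    intercept = float(theta[-1])
    return GPLMCoefficients(beta=beta, alpha=alpha, gamma=gamma, intercept=intercept)


def _pack(coef: GPLMCoefficients, data: GPLMDataset, design, active) -> np.ndarray:
    nb = design.n_columns if design is not None else 0
    parts = [coef.beta[active]] if len(active) else []
    if data.qw:
        parts.append(coef.alpha)
    if nb:
        parts.append(coef.gamma)
    parts.append(np.array([coef.intercept]))
    return np.concatenate(parts) if parts else np.array([coef.intercept])


def _solve_weighted(data, design, active, beta_weights, config, theta0=None):
    """One penalized fit over the given active coordinates.

    Returns ``(GPLMCoefficients, SolveResult)``.  The unpenalized block
    (alpha, gamma, intercept) carries the tiny stability ridge, which guards
    logistic fits against separation.
    """
    active = np.asarray(active, dtype=int)
    nb = design.n_columns if design is not None else 0
    n_unpen = data.qw + nb + 1
    A = _assemble(data, design, active)
    eps = config.eps_stab if config.stabilize else 0.0
    weights = np.concatenate([np.asarray(beta_weights, dtype=float),
                              np.full(n_unpen, eps)])
    method = config.solver
    if method == "auto":
        can_woodbury = len(active) and np.all(np.asarray(beta_weights) > 0)
        method = "woodbury" if (len(active) >= config.large_p_threshold
                                and can_woodbury) else "newton"
    res = _solvers.solve_penalized(
        data.y, A, weights, data.family, theta0=theta0,
        method=method, dense_block=len(active),
        tol=config.inner_tol, max_iter=config.max_inner,
    )
    if res.objective > res.objective_start + 1e-6 * (1.0 + abs(res.objective_start)):
        raise FitError("inner solver increased the penalized objective")
    return _unpack(res.theta, data, design, active), res


# ---------------------------------------------------------------------------
# public fitting operations
# ---------------------------------------------------------------------------

def ridge_init(data: GPLMDataset, design: SieveDesign | None = None,
               xi_n: float = 1.0, config: BARConfig | None = None) -> GPLMCoefficients:
    """Minimize ``-2*loglik + xi_n * ||beta||^2`` (only ``beta`` penalized)."""
    if xi_n <= 0:
        raise ValueError("xi_n must be positive")
    config = config or BARConfig(xi_n=xi_n)
    active = np.arange(data.p)
    coef, _ = _solve_weighted(data, design, active, np.full(data.p, xi_n), config)
    return coef


def bar_step(data: GPLMDataset, design: SieveDesign | None,
             beta_prev: np.ndarray, lambda_n: float,
             config: BARConfig | None = None,
             theta0: np.ndarray = None) -> GPLMCoefficients:
    """One reweighted-ridge update with weights ``lambda_n / beta_prev**2``.

    Coordinates with ``|beta_prev| < drop_threshold`` are treated as dropped
    and held at exactly zero; alpha, gamma and the intercept are refit
    unpenalized.  An empty active set degenerates to the X-free fit.
    """
    config = config or BARConfig()
    beta_prev = np.asarray(beta_prev, dtype=float)
    if beta_prev.shape != (data.p,):
        raise ValueError(f"beta_prev must have length {data.p}")
    if lambda_n < 0:
        raise ValueError("lambda_n must be nonnegative")
    active = np.flatnonzero(np.abs(beta_prev) >= config.drop_threshold)
    if lambda_n == 0.0:
        weights = np.zeros(len(active))
    else:
        weights = lambda_n / beta_prev[active] ** 2
    coef, _ = _solve_weighted(data, design, active, weights, config, theta0=theta0)
    return coef


def fit_gplm_bar(data: GPLMDataset, spec: SieveBasisSpec | None = None,
                 config: BARConfig | None = None,
                 design: SieveDesign | None = None) -> FitResult:
    """Full selection-and-estimation loop: ridge start, then reweighted ridge
    refits until the ``beta`` iterates stabilize.

    Deterministic given the data and configuration.  Dropped coordinates are
    exact zeros in the returned result.
    """
    config = config or BARConfig()
    if design is None:
        if data.qz:
            if spec is None:
                spec = SieveBasisSpec.from_data(data.Z, degree=config.degree)
            design = build_sieve_design(data.Z, spec)
        else:
            spec = spec or SieveBasisSpec(degrees=(), lower=(), upper=())
    else:
        spec = design.spec
    lambda_n = (config.lambda_value if config.lambda_rule == "fixed"
                else choose_lambda(config.lambda_rule, n=data.n, p=data.p,
                                   value=config.lambda_value))
    if lambda_n is None:
        raise ValueError("lambda_rule 'fixed' requires lambda_value")

    coef = ridge_init(data, design, xi_n=config.xi_n, config=config)
    beta_prev = coef.beta
    converged = False
    n_outer = 0
    res = None
    for n_outer in range(1, config.max_outer + 1):
        active = np.flatnonzero(np.abs(beta_prev) >= config.drop_threshold)
        weights = (lambda_n / beta_prev[active] ** 2 if lambda_n > 0
                   else np.zeros(len(active)))
        theta0 = _pack(coef, data, design, active)
        coef, res = _solve_weighted(data, design, active, weights, config,
                                    theta0=theta0)
        # zero-preservation: dropped coordinates can never resurrect
        beta_new = coef.beta
        change = float(np.max(np.abs(beta_new - beta_prev))) if data.p else 0.0
        beta_prev = beta_new
        if change < config.eps_outer:
            converged = True
            break
    if not converged:
        logger.warning("outer loop hit the %d-iteration cap (last change above "
                       "eps_outer)", config.max_outer)

    active_set = np.flatnonzero(np.abs(coef.beta) >= config.drop_threshold)
    beta_final = np.zeros(data.p)
    beta_final[active_set] = coef.beta[active_set]
    coef = GPLMCoefficients(beta=beta_final, alpha=coef.alpha,
                            gamma=coef.gamma, intercept=coef.intercept)
    ll = sieve_loglik(data, coef, design)
    objective = res.objective if res is not None else float("nan")
    return FitResult(coefficients=coef, active_set=active_set, n_outer=n_outer,
                     converged=converged, objective=objective, loglik=ll,
                     spec=spec, lambda_n=float(lambda_n), xi_n=config.xi_n,
                     family=data.family, x_center=data.x_center,
                     x_scale=data.x_scale)


def fit_unpenalized(data: GPLMDataset, spec: SieveBasisSpec | None = None,
                    support=None, config: BARConfig | None = None,
                    design: SieveDesign | None = None) -> FitResult:
    """Unpenalized (oracle-style) fit restricted to ``support`` columns of X.

    Only the tiny stability ridge is applied.  ``support=None`` uses all
    columns.
    """
    config = config or BARConfig()
    if design is None and data.qz:
        if spec is None:
            spec = SieveBasisSpec.from_data(data.Z, degree=config.degree)
        design = build_sieve_design(data.Z, spec)
    if design is not None:
        spec = design.spec
    elif spec is None:
        spec = SieveBasisSpec(degrees=(), lower=(), upper=())
    active = (np.arange(data.p) if support is None
              else np.asarray(sorted(support), dtype=int))
    eps = config.eps_stab if config.stabilize else 0.0
    coef, res = _solve_weighted(data, design, active,
                                np.full(len(active), eps), config)
    return FitResult(coefficients=coef, active_set=active, n_outer=1,
                     converged=True, objective=res.objective, loglik=res.loglik,
                     spec=spec, lambda_n=0.0, xi_n=config.xi_n,
                     family=data.family, x_center=data.x_center,
                     x_scale=data.x_scale)


def predict(fit: FitResult, X, W=None, Z=None) -> np.ndarray:
    """Mean response on new covariates (probabilities for logistic fits).

    New X columns are standardized with the training centers/scales; new Z
    values are clamped to the training basis ranges.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    coef = fit.coefficients
    if X.shape[1] != coef.beta.shape[0]:
        raise ValueError(f"X must have {coef.beta.shape[0]} columns")
    Xs = (X - fit.x_center) / fit.x_scale
    eta = fit.coefficients.intercept + Xs @ coef.beta
    if coef.alpha.size:
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape != (n, coef.alpha.shape[0]):
            raise ValueError(f"W must have shape ({n}, {coef.alpha.shape[0]})")
        eta = eta + W @ coef.alpha
    if fit.spec.n_covariates:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, np.newaxis]
        if Z.shape != (n, fit.spec.n_covariates):
            raise ValueError(f"Z must have shape ({n}, {fit.spec.n_covariates})")
        design = build_sieve_design(Z, fit.spec, clamp=True)
        eta = eta + design.matrix @ coef.gamma
    if fit.family == "logistic":
        from scipy.special import expit
        return expit(eta)
    return np.exp(eta)


def bootstrap_se(data: GPLMDataset, spec: SieveBasisSpec | None = None,
                 config: BARConfig | None = None, B: int = 100,
                 seed: int = 0) -> BootstrapResult:
    """Nonparametric bootstrap standard errors of the fitted coefficients.

    Resamples the ``n`` observations with replacement ``B`` times, refits the
    full selection loop on each resample, and returns the sample standard
    deviation of each unpenalized coefficient and of each ``beta`` coordinate
    selected by the fit on the original data.  Resamples whose refit fails
    are excluded and counted.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    config = config or BARConfig()
    full = fit_gplm_bar(data, spec=spec, config=config)
    active = full.active_set
    rng = np.random.default_rng(seed)
    betas, alphas, gammas, icepts = [], [], [], []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, data.n, data.n)
        try:
            d_b = GPLMDataset.from_arrays(
                data.y[idx], data.X[idx], data.W[idx] if data.qw else None,
                data.Z[idx] if data.qz else None, family=data.family)
            fit_b = fit_gplm_bar(d_b, spec=full.spec, config=config)
        except (FitError, ValueError) as exc:
            n_failed += 1
            logger.warning("bootstrap resample failed and was excluded: %s", exc)
            continue
        betas.append(fit_b.coefficients.beta[active])
        alphas.append(fit_b.coefficients.alpha)
        gammas.append(fit_b.coefficients.gamma)
        icepts.append(fit_b.coefficients.intercept)
    if len(betas) < 2:
        raise FitError(f"only {len(betas)} bootstrap refits succeeded")
    betas = np.array(betas)
    alphas = np.array(alphas)
    gammas = np.array(gammas)
    icepts = np.array(icepts)
    return BootstrapResult(
        se_beta=betas.std(axis=0, ddof=1),
        active_set=active,
        se_alpha=alphas.std(axis=0, ddof=1) if data.qw else np.empty(0),
        se_gamma=gammas.std(axis=0, ddof=1) if gammas.size else np.empty(0),
        se_intercept=float(icepts.std(ddof=1)),
        n_resamples=len(betas),
        n_failed=n_failed,
    )
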