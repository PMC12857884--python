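"""Shared fixtures: small random instances and session-scoped study runs."""

import numpy as np
import pytest

import sievebar as sb

#: fixed base seed for all replicated acceptance studies
ACCEPT_SEED = 20_250_906


def make_small_instance(seed, n=60, p=4, with_w=False, with_z=False,
                        family="logistic"):
    """A tiny well-conditioned dataset for solver-oracle comparisons."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.uniform(-1.0, 1.0, p)
    eta = X @ beta
    W = Z = None
    if with_w:
        W = rng.binomial(1, 0.5, (n, 2)).astype(float)
        eta = eta + W @ np.array([0.8, -0.5])
    if with_z:
        Z = rng.uniform(0.0, 1.0, (n, 1))
        eta = eta + 0.5 * (Z[:, 0] - 0.5) ** 2
    if family == "logistic":
        from scipy.special import expit
        y = rng.binomial(1, expit(eta)).astype(float)
    else:
        y = rng.poisson(np.exp(np.clip(eta, None, 3.0))).astype(float)
    return sb.GPLMDataset.from_arrays(y, X, W, Z, family=family)


@pytest.fixture(scope="session")
def study_s1_n600():
    """Scenario 1, n=600, p=300: BIC + AIC + oracle on shared data, 100 reps."""
    return sb.run_study("1", 600, 300, reps=100,
                        methods=["bar_bic", "bar_aic", "oracle"],
                        base_seed=ACCEPT_SEED)


@pytest.fixture(scope="session")
def study_s1_n800():
    """Scenario 1, n=800, p=300: BIC, 100 reps."""
    return sb.run_study("1", 800, 300, reps=100, methods=["bar_bic"],
                        base_seed=ACCEPT_SEED + 1_000)


@pytest.fixture(scope="session")
def study_s2_n800():
    """Scenario 2 (weak signals), n=800, p=300: AIC, 100 reps."""
    return sb.run_study("2", 800, 300, reps=100, methods=["bar_aic"],
                        base_seed=ACCEPT_SEED + 2_000)


@pytest.fixture(scope="session")
def study_s3_n600_p2000():
    """Scenario 3, n=600, p=2000: BIC, 25 reps."""
    return sb.run_study("3", 600, 2000, reps=25, methods=["bar_bic"],
                        base_seed=ACCEPT_SEED + 3_000)
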