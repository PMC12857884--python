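"""Bernstein-polynomial sieve bases for additive nonparametric covariate effects.

Each smooth additive effect ``psi_j`` of a continuous covariate ``z_j`` is
approximated inside a finite-dimensional sieve spanned by the Bernstein basis
of degree ``m_j`` on the observed range ``[c_j, u_j]``::

    psi_j(z) = sum_{k=0..m_j} gamma_jk * B_k(z; m_j, c_j, u_j),
    B_k(z; m, c, u) = C(m, k) t^k (1 - t)^(m - k),   t = (z - c) / (u - c).

The basis is nonnegative, forms a partition of unity, and needs no knot
placement.  Identifiability of the additive decomposition is enforced by
centering every basis column at the interval midpoint, which pins
``psi_j(mid_j) = 0`` exactly for any coefficient vector; a free global
intercept picks up the level.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.stats import binom

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidRangeError",
    "InvalidDegreeError",
    "SieveBasisSpec",
    "SieveDesign",
    "bernstein_basis",
    "build_sieve_design",
    "evaluate_psi",
]

#: default Bernstein degree (m + 1 = 4 basis functions per smooth effect)
DEFAULT_DEGREE = 3


class InvalidRangeError(ValueError):
    """Raised when a basis interval is degenerate (c >= u)."""


class InvalidDegreeError(ValueError):
    """Raised when a Bernstein degree is below 1."""


def bernstein_basis(z, m: int, c: float, u: float, clamp: bool = True) -> np.ndarray:
    """Evaluate the degree-``m`` Bernstein basis on ``[c, u]`` at ``z``.

    Parameters
    ----------
    z : scalar or array-like
        Evaluation points.  Values outside ``[c, u]`` are clamped to the
        nearest endpoint when ``clamp`` is true (the default), otherwise an
        error is raised.
    m : int
        Polynomial degree; the basis has ``m + 1`` functions.
    c, u : float
        Interval endpoints, ``c < u``.

    Returns
    -------
    ndarray
        Shape ``(m + 1,)`` for scalar ``z`` and ``z.shape + (m + 1,)``
        otherwise.  Entries are in ``[0, 1]`` and sum to one.
    """
    if m < 1:
        raise InvalidDegreeError(f"Bernstein degree must be >= 1, got {m}")
    if not c < u:
        raise InvalidRangeError(f"need c < u, got c={c!r}, u={u!r}")
    z_arr = np.asarray(z, dtype=float)
    t = (z_arr - c) / (u - c)
    out_of_range = (t < 0.0) | (t > 1.0)
    if np.any(out_of_range):
        if not clamp:
            raise InvalidRangeError(
                f"{int(out_of_range.sum())} evaluation point(s) outside [{c}, {u}]"
            )
        logger.warning(
            "clamping %d evaluation point(s) to the basis range [%g, %g]",
            int(out_of_range.sum()), c, u,
        )
        t = np.clip(t, 0.0, 1.0)
    k = np.arange(m + 1)
    # B_k(t) = C(m,k) t^k (1-t)^(m-k) is the Binomial(m, t) pmf at k.
    vals = binom.pmf(k, m, t[..., np.newaxis])
    if z_arr.ndim == 0:
        return vals.reshape(m + 1)
    return vals


@dataclasses.dataclass(frozen=True)
class SieveBasisSpec:
    """Per-covariate Bernstein expansion metadata.

    Attributes
    ----------
    degrees : tuple of int
        Degree ``m_j`` for each continuous covariate (``m_j + 1`` columns).
    lower, upper : tuple of float
        Interval endpoints ``c_j < u_j`` in covariate units.
    center : bool
        Whether basis columns are centered at the interval midpoint so that
        ``psi_j(mid_j) = 0`` exactly.
    """

    degrees: tuple
    lower: tuple
    upper: tuple
    center: bool = True

    def __post_init__(self):
        degrees = tuple(int(m) for m in self.degrees)
        lower = tuple(float(c) for c in self.lower)
        upper = tuple(float(u) for u in self.upper)
        object.__setattr__(self, "degrees", degrees)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if not (len(degrees) == len(lower) == len(upper)):
            raise ValueError("degrees, lower and upper must have equal length")
        for j, (m, c, u) in enumerate(zip(degrees, lower, upper)):
            if m < 1:
                raise InvalidDegreeError(f"covariate {j}: degree must be >= 1, got {m}")
            if not c < u:
                raise InvalidRangeError(f"covariate {j}: need c < u, got c={c}, u={u}")

    @classmethod
    def from_data(cls, Z, degree=DEFAULT_DEGREE, center: bool = True) -> "SieveBasisSpec":
        """Build a spec from observed data, one interval per column of ``Z``.

        Ranges default to the observed column minima/maxima.  ``degree`` may
        be a single int (applied to every covariate) or a per-column sequence.
        """
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.ndim != 2:
            raise ValueError("Z must be a 2-D array")
        qz = Z.shape[1]
        if isinstance(degree, (int, np.integer)):
            degrees = (int(degree),) * qz
        else:
            degrees = tuple(int(m) for m in degree)
            if len(degrees) != qz:
                raise ValueError(f"got {len(degrees)} degrees for {qz} covariates")
        lo = Z.min(axis=0)
        hi = Z.max(axis=0)
        for j in range(qz):
            if not lo[j] < hi[j]:
                raise InvalidRangeError(
                    f"column {j} of Z is constant (value {lo[j]}); no basis range"
                )
        return cls(degrees=degrees, lower=tuple(lo), upper=tuple(hi), center=center)

    @property
    def n_covariates(self) -> int:
        return len(self.degrees)

    @property
    def midpoints(self) -> tuple:
        return tuple((c + u) / 2.0 for c, u in zip(self.lower, self.upper))

    @property
    def n_columns(self) -> int:
        return sum(m + 1 for m in self.degrees)

    def block_slice(self, j: int) -> slice:
        """Column slice of the expanded design owned by covariate ``j``."""
        if not 0 <= j < self.n_covariates:
            raise IndexError(f"covariate index {j} out of range")
        start = sum(m + 1 for m in self.degrees[:j])
        return slice(start, start + self.degrees[j] + 1)


@dataclasses.dataclass(frozen=True)
class SieveDesign:
    """Expanded (and optionally centered) sieve design.

    ``matrix`` has one row per observation and ``spec.n_columns`` columns;
    ``midpoint_rows[j]`` holds the *uncentered* basis evaluated at the
    interval midpoint of covariate ``j`` (the row subtracted during
    centering).
    """

    matrix: np.ndarray
    spec: SieveBasisSpec
    midpoint_rows: tuple

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def block_slice(self, j: int) -> slice:
        return self.spec.block_slice(j)

    def column_index(self, j: int, k: int) -> int:
        """Flat column position of basis function ``k`` of covariate ``j``."""
        sl = self.spec.block_slice(j)
        if not 0 <= k <= self.spec.degrees[j]:
            raise IndexError(f"basis index {k} out of range for covariate {j}")
        return sl.start + k


def build_sieve_design(Z, spec: SieveBasisSpec | None = None, *,
                       degree=DEFAULT_DEGREE, center: bool = True,
                       clamp: bool = False) -> SieveDesign:
    """Expand continuous covariates into Bernstein basis blocks.

    Parameters
    ----------
    Z : (n, qz) array
        Continuous covariates, one column per smooth effect.
    spec : SieveBasisSpec, optional
        Expansion metadata; computed from the observed ranges of ``Z`` when
        omitted.
    clamp : bool
        Clamp values outside the spec ranges (used at prediction time; at
        build time out-of-range values indicate a spec/data mismatch).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, np.newaxis]
    if spec is None:
        spec = SieveBasisSpec.from_data(Z, degree=degree, center=center)
    if Z.shape[1] != spec.n_covariates:
        raise ValueError(
            f"Z has {Z.shape[1]} columns but spec covers {spec.n_covariates}"
        )
    blocks = []
    midpoint_rows = []
    for j in range(spec.n_covariates):
        m, c, u = spec.degrees[j], spec.lower[j], spec.upper[j]
        B = bernstein_basis(Z[:, j], m, c, u, clamp=clamp)
        mid_row = bernstein_basis(spec.midpoints[j], m, c, u)
        midpoint_rows.append(mid_row)
        if spec.center:
            B = B - mid_row
        blocks.append(B)
    matrix = np.hstack(blocks) if blocks else np.empty((Z.shape[0], 0))
    return SieveDesign(matrix=matrix, spec=spec, midpoint_rows=tuple(midpoint_rows))


def evaluate_psi(gamma_block, grid, spec: SieveBasisSpec, j: int = 0) -> np.ndarray:
    """Evaluate the fitted smooth effect of covariate ``j`` on a grid.

    ``gamma_block`` is the length-``m_j + 1`` coefficient block; centering of
    the spec is honored, so centered fits satisfy ``psi_hat(mid_j) == 0``
    exactly.
    """
    gamma_block = np.asarray(gamma_block, dtype=float)
    m, c, u = spec.degrees[j], spec.lower[j], spec.upper[j]
    if gamma_block.shape != (m + 1,):
        raise ValueError(
            f"gamma block for covariate {j} must have length {m + 1}, "
            f"got {gamma_block.shape}"
        )
    grid = np.asarray(grid, dtype=float)
    B = bernstein_basis(grid, m, c, u, clamp=True)
    if spec.center:
        B = B - bernstein_basis(spec.midpoints[j], m, c, u)
    return B @ gamma_block
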