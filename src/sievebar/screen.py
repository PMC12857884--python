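"""SNP pre-screening: allele-frequency filtering and univariate logistic scans.

Dimension reduction before the penalized fit proceeds in two stages, in this
order:

1. remove SNPs whose minor allele frequency (MAF) is below a threshold
   (default 0.1; the boundary is inclusive, i.e. MAF exactly at the
   threshold is retained);
2. keep only SNPs whose slope in a single-SNP logistic regression has a Wald
   p-value below a threshold (default 0.1).

Counts at each stage are recorded so the pipeline's reduction path can be
audited.  Missing dosages are allowed (NaN) and excluded per SNP.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import _solvers
from ._solvers import FitError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "maf_filter",
    "univariate_screen",
    "transform_continuous",
    "screen_pipeline",
]

#: |slope| beyond which a single-SNP logistic fit is treated as separated
_SEPARATION_BOUND = 15.0
#: ridge applied when refitting a separated SNP
_SEPARATION_RIDGE = 1e-4


@dataclasses.dataclass(frozen=True)
class GenotypeMatrix:
    """Sample-by-SNP dosage matrix with identifiers.

    Dosages live in ``[0, 2]`` (typically 0/1/2 allele counts); missing
    entries are ``NaN`` and are reported at validation.
    """

    values: np.ndarray
    snp_ids: tuple
    sample_ids: tuple

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        n, p = values.shape
        if len(self.snp_ids) != p:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        n_missing = int(np.isnan(values).sum())
        if n_missing:
            logger.info("genotype matrix has %d missing dosages", n_missing)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(values=df.to_numpy(dtype=float),
                   snp_ids=tuple(df.columns), sample_ids=tuple(df.index.astype(str)))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def select(self, keep_idx) -> "GenotypeMatrix":
        keep_idx = np.asarray(keep_idx, dtype=int)
        return GenotypeMatrix(values=self.values[:, keep_idx],
                              snp_ids=tuple(self.snp_ids[i] for i in keep_idx),
                              sample_ids=self.sample_ids)


def snp_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from mean dosage over non-missing entries."""
    d = dosages[np.isfinite(dosages)]
    if d.size == 0:
        return float("nan")
    f = float(d.mean()) / 2.0
    return min(f, 1.0 - f)


def maf_filter(G: GenotypeMatrix, threshold: float = 0.1):
    """Keep SNPs with minor allele frequency >= ``threshold``.

    Returns ``(filtered GenotypeMatrix, report DataFrame)``; the report lists
    every SNP with its MAF, whether it was kept, and the removal reason.
    All-missing columns are removed with reason ``"no data"``.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    if G.p == 0:
        raise ValueError("empty genotype matrix")
    mafs = np.array([snp_maf(G.values[:, j]) for j in range(G.p)])
    kept = np.zeros(G.p, dtype=bool)
    reasons = []
    for j, maf in enumerate(mafs):
        if np.isnan(maf):
            reasons.append("no data")
        elif maf < threshold:
            reasons.append(f"MAF {maf:.4g} < {threshold}")
        else:
            kept[j] = True
            reasons.append("")
    report = pd.DataFrame({"snp": G.snp_ids, "maf": mafs, "kept": kept,
                           "reason": reasons})
    return G.select(np.flatnonzero(kept)), report


def _single_snp_logistic(y, g, ridge=0.0):
    """Intercept + slope logistic fit; returns (slope, se, pvalue).

    The p-value is a Wald test in the regular case.  Under the ridge-
    stabilized refit of a separated SNP the Wald statistic is unreliable
    (Hauck-Donner), so a likelihood-ratio test against the intercept-only
    model is used instead.
    """
    A = np.column_stack([np.ones_like(g), g])
    weights = np.array([ridge, ridge])
    res = _solvers.solve_penalized(y, A, weights, "logistic",
                                   tol=1e-10, max_iter=60)
    slope = float(res.theta[1])
    from scipy.special import expit
    mu = expit(A @ res.theta)
    d = mu * (1.0 - mu)
    H = (A * d[:, None]).T @ A
    H[np.diag_indices_from(H)] += ridge
    cov = np.linalg.inv(H)
    se = float(np.sqrt(cov[1, 1]))
    if ridge > 0:
        null = _solvers.solve_penalized(y, A[:, :1], weights[:1], "logistic",
                                        tol=1e-10, max_iter=60)
        lr = max(2.0 * (res.loglik - null.loglik), 0.0)
        pvalue = float(stats.chi2.sf(lr, df=1))
    else:
        z = slope / se if se > 0 else np.inf
        pvalue = 2.0 * stats.norm.sf(abs(z))
    return slope, se, pvalue


def univariate_screen(y, G: GenotypeMatrix, p_threshold: float = 0.1,
                      covariates=None):
    """Single-SNP logistic screening at the given Wald p-value threshold.

    Each SNP is regressed (with an intercept, plus optional fixed
    ``covariates``) on the binary response by Newton iteration; the SNP is
    retained iff the slope's Wald p-value is strictly below ``p_threshold``.
    Perfectly separating SNPs are refit with a small stabilizing ridge and
    flagged.  Returns ``(retained snp-id list, per-SNP stats DataFrame)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != G.n:
        raise ValueError("y length must match genotype rows")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != G.n:
            raise ValueError("covariate rows must match genotype rows")

    rows = []
    for j in range(G.p):
        g = G.values[:, j]
        mask = np.isfinite(g)
        yj, gj = y[mask], g[mask]
        flagged = False
        try:
            if cov is None:
                slope, se, pval = _single_snp_logistic(yj, gj)
            else:
                slope, se, pval = _adjusted_snp_logistic(yj, gj, cov[mask])
            if abs(slope) > _SEPARATION_BOUND:
                raise FitError("separated")
        except (FitError, np.linalg.LinAlgError):
            flagged = True
            logger.warning("SNP %s shows separation; ridge-stabilized refit used",
                           G.snp_ids[j])
            if cov is None:
                slope, se, pval = _single_snp_logistic(yj, gj, ridge=_SEPARATION_RIDGE)
            else:
                slope, se, pval = _adjusted_snp_logistic(yj, gj, cov[mask],
                                                         ridge=_SEPARATION_RIDGE)
        rows.append({"snp": G.snp_ids[j], "estimate": slope, "se": se,
                     "pvalue": pval, "separation_flag": flagged,
                     "n_used": int(mask.sum())})
    table = pd.DataFrame(rows)
    retained = [r["snp"] for r in rows if r["pvalue"] < p_threshold]
    return retained, table


def _adjusted_snp_logistic(y, g, cov, ridge=0.0):
    A = np.column_stack([np.ones_like(g), g, cov])
    weights = np.full(A.shape[1], ridge)
    res = _solvers.solve_penalized(y, A, weights, "logistic",
                                   tol=1e-10, max_iter=60)
    from scipy.special import expit
    mu = expit(A @ res.theta)
    d = mu * (1.0 - mu)
    H = (A * d[:, None]).T @ A
    H[np.diag_indices_from(H)] += ridge
    cov_mat = np.linalg.inv(H)
    slope = float(res.theta[1])
    se = float(np.sqrt(cov_mat[1, 1]))
    if ridge > 0:
        A0 = np.delete(A, 1, axis=1)
        null = _solvers.solve_penalized(y, A0, np.delete(weights, 1),
                                        "logistic", tol=1e-10, max_iter=60)
        lr = max(2.0 * (res.loglik - null.loglik), 0.0)
        return slope, se, float(stats.chi2.sf(lr, df=1))
    z = slope / se if se > 0 else np.inf
    return slope, se, 2.0 * stats.norm.sf(abs(z))


def transform_continuous(values, rule: str = "identity") -> np.ndarray:
    """Identity or natural-log transform of a continuous covariate."""
    values = np.asarray(values, dtype=float)
    if rule == "identity":
        return values.copy()
    if rule == "log":
        bad = np.flatnonzero(values <= 0)
        if bad.size:
            raise ValueError(
                f"log transform requires positive values; row {int(bad[0])} "
                f"has value {values[bad[0]]!r}")
        return np.log(values)
    raise ValueError(f"unknown rule {rule!r}; use 'identity' or 'log'")


def screen_pipeline(y, G: GenotypeMatrix, maf_threshold: float = 0.1,
                    p_threshold: float = 0.1, covariates=None):
    """MAF filter followed by univariate screening, with stage counts.

    Returns ``(screened GenotypeMatrix, dict)`` where the dict holds the
    per-stage SNP counts and the per-SNP tables from both stages.
    """
    G1, maf_report = maf_filter(G, threshold=maf_threshold)
    retained, stats_table = univariate_screen(y, G1, p_threshold=p_threshold,
                                              covariates=covariates)
    keep_idx = [i for i, s in enumerate(G1.snp_ids) if s in set(retained)]
    G2 = G1.select(keep_idx)
    counts = {"input": G.p, "after_maf": G1.p, "after_screen": G2.p}
    logger.info("screening stages: %s", counts)
    return G2, {"counts": counts, "maf_report": maf_report,
                "screen_table": stats_table, "retained": retained}
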