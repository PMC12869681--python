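"""Single-variant case-control association and meta-analysis.

Common and low-frequency SVs (MAF > 0.5%, Hardy-Weinberg-consistent) are
tested one at a time with a fixed-effects logistic regression of disease
status on allele dosage, adjusted for sex, ancestry principal components,
and technical batch covariates. Per-ancestry results are combined with the
sample-size-weighted Stouffer method. The tag-SNP scan reports SVs in LD
(r^2 > 0.4) with known GWAS index SNPs, and conditional models include the
partner variant's dosage as a covariate to assess signal independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from svcohort.popstruct import em_ld

MAX_ABS_BETA = 15.0  # |log-odds| beyond this is treated as separation


@dataclass
class AssociationResult:
    site_id: str
    n: int
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    z: float
    p: float
    af_by_group: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    used_score_test: bool = False


@dataclass(frozen=True)
class AnalysisFilters:
    maf_min: float = 0.005
    hwe_alpha: float | None = None  # None -> Bonferroni 0.05 / n sites

    def __post_init__(self) -> None:
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")


class CollinearityError(ValueError):
    pass


def _logistic_fit(y: np.ndarray, X: np.ndarray, tol: float = 1e-10,
                  max_iter: int = 50) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson ML logistic fit; returns (beta, cov, converged)."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError("design matrix is rank deficient")
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        XtWX = X.T @ (X * W[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    cov = np.linalg.pinv(X.T @ (X * W[:, None]))
    return beta, cov, converged


def score_test(y: np.ndarray, g: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Rao score test of a variant in the null logistic model y ~ X.

    Returns the signed z statistic and two-sided p; no per-variant fit is
    required, which keeps the test stable under quasi-separation.
    """
    beta0, _, _ = _logistic_fit(y, X)
    mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta0, -30, 30)))
    W = mu * (1 - mu)
    U = float(g @ (y - mu))
    XtWX_inv = np.linalg.pinv(X.T @ (X * W[:, None]))
    gW = g * W
    V = float(g @ gW - (gW @ X) @ XtWX_inv @ (X.T @ gW))
    if V <= 0:
        return 0.0, 1.0
    z = U / math.sqrt(V)
    return z, 2.0 * stats.norm.sf(abs(z))


def logistic_assoc(y: Sequence[int], g: Sequence[float], X: np.ndarray,
                   site_id: str = "", af_by_group: dict[str, float] | None = None,
                   ) -> AssociationResult:
    """Wald test of one variant in a fixed-effects logistic model.

    ``X`` must include the intercept column. Under quasi-complete
    separation (diverging |beta| or non-convergence) the p-value falls
    back to the score test and the result is flagged.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("variant dosage is constant")
    ok = ~np.isnan(g)
    y, g, X = y[ok], g[ok], np.asarray(X, dtype=float)[ok]
    design = np.column_stack([X, g])
    try:
        beta_all, cov, converged = _logistic_fit(y, design)
    except CollinearityError:
        raise
    beta = float(beta_all[-1])
    se = float(math.sqrt(max(cov[-1, -1], 0.0)))
    separated = (not converged) or abs(beta) > MAX_ABS_BETA or se == 0
    if separated:
        z, p = score_test(y, g, X)
        return AssociationResult(site_id, len(y), beta, se, math.exp(min(beta, 700)),
                                 (float("nan"), float("nan")), z, p,
                                 af_by_group or {}, converged=converged,
                                 used_score_test=True)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationResult(
        site_id=site_id, n=len(y), beta=beta, se=se, or_=math.exp(beta),
        ci95=(math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        z=float(z), p=float(max(p, 5e-324)), af_by_group=af_by_group or {},
    )


def conditional_assoc(y, g, X, g_cond, site_id: str = "") -> AssociationResult:
    """Association of ``g`` with the conditioning variant's dosage in the model."""
    g_cond = np.asarray(g_cond, dtype=float)
    g_arr = np.asarray(g, dtype=float)
    if np.ptp(g_cond) == 0:
        raise CollinearityError("conditioning dosage is constant")
    corr = np.corrcoef(g_arr, g_cond)[0, 1]
    if abs(corr) > 1 - 1e-10:
        raise CollinearityError("variant and conditioning dosage are collinear")
    X_cond = np.column_stack([np.asarray(X, dtype=float), g_cond])
    return logistic_assoc(y, g, X_cond, site_id=site_id)


def tag_ld_scan(sv_dosages: np.ndarray, sv_info: pd.DataFrame,
                snp_dosages: np.ndarray, snp_info: pd.DataFrame,
                r2_min: float = 0.4) -> pd.DataFrame:
    """All same-chromosome (SV, tag SNP) pairs with EM r^2 strictly above ``r2_min``.

    ``sv_info``/``snp_info`` need columns ``id`` and ``chrom`` aligned with
    the dosage matrix columns.
    """
    rows = []
    for j_sv in range(sv_dosages.shape[1]):
        for j_snp in range(snp_dosages.shape[1]):
            if sv_info["chrom"].iloc[j_sv] != snp_info["chrom"].iloc[j_snp]:
                continue
            try:
                ld = em_ld(sv_dosages[:, j_sv], snp_dosages[:, j_snp])
            except ValueError:
                continue
            if ld.r2 > r2_min:
                rows.append({"sv": sv_info["id"].iloc[j_sv],
                             "snp": snp_info["id"].iloc[j_snp],
                             "r2": ld.r2, "D": ld.D, "D_prime": ld.D_prime})
    return pd.DataFrame(rows, columns=["sv", "snp", "r2", "D", "D_prime"])


def haplotype_phase(sv_dosage: Sequence[float], snp_dosage: Sequence[float],
                    risk_is_alt: bool = True, d_prime_min: float = 0.5) -> str:
    """Which haplotype background carries the SV relative to the risk allele.

    Returns ``same_haplotype`` when the oriented D is positive with
    |D'| > ``d_prime_min``, ``opposite_haplotype`` for negative D, and
    ``ambiguous`` otherwise.
    """
    ld = em_ld(sv_dosage, snp_dosage)
    D = ld.D if risk_is_alt else -ld.D
    if abs(ld.D_prime) > d_prime_min:
        if D > 0:
            return "same_haplotype"
        if D < 0:
            return "opposite_haplotype"
    return "ambiguous"


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance level controlling FWER over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def stouffer_meta(z_scores: Sequence[float], n_samples: Sequence[float],
                  ) -> tuple[float, float]:
    """Sample-size-weighted Stouffer combination of signed z statistics.

    z_meta = sum(sqrt(n_i) z_i) / sqrt(sum n_i); two-sided p. A single
    group passes through unchanged.
    """
    z = np.asarray(z_scores, dtype=float)
    n = np.asarray(n_samples, dtype=float)
    if len(z) == 0:
        raise ValueError("no groups")
    if len(z) == 1:
        import warnings
        warnings.warn("single group: meta-analysis is a passthrough")
        return float(z[0]), float(2.0 * stats.norm.sf(abs(z[0])))
    w = np.sqrt(n)
    z_meta = float((w * z).sum() / math.sqrt(n.sum()))
    return z_meta, float(2.0 * stats.norm.sf(abs(z_meta)))
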