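"""Two-locus LD by EM, LD pruning, genotype PCA, and the PC-vs-batch screen.

LD between unphased diallelic loci is estimated with the classic
composite-phase EM over the 3x3 genotype table: the only ambiguous cell is
the double heterozygote, whose two phase resolutions are weighted by the
current haplotype-frequency estimates. D, D' and r^2 follow from the
converged frequencies.

PCA operates on the dosage matrix after MAF, Hardy-Weinberg, and LD-pruning
filters, with dosages centered at 2p and scaled by sqrt(2p(1-p)) so each
site contributes unit drift variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from svcohort.cohort_qc import hwe_exact


@dataclass
class LDResult:
    hap_freqs: tuple[float, float, float, float]  # AB, Ab, aB, ab (A/B = alt alleles)
    D: float
    D_prime: float
    r2: float
    n_iter: int


def _genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a = g1[ok].astype(int)
    b = g2[ok].astype(int)
    n = np.zeros((3, 3))
    np.add.at(n, (a, b), 1)
    return n


def em_ld(g1: Sequence[float], g2: Sequence[float], tol: float = 1e-8,
          max_iter: int = 1000) -> LDResult:
    """Estimate two-locus haplotype frequencies and LD from unphased dosages.

    Raises ``ValueError`` on monomorphic input (r^2 undefined).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n = _genotype_table(g1, g2)
    n_hap = 2 * n.sum()
    pA = (2 * n[2, :].sum() + n[1, :].sum()) / n_hap
    pB = (2 * n[:, 2].sum() + n[:, 1].sum()) / n_hap
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic site: r^2 undefined")
    # f[0]=f_AB, f[1]=f_Ab, f[2]=f_aB, f[3]=f_ab
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    n_dh = n[1, 1]
    it = 0
    for it in range(1, max_iter + 1):
        denom = f[0] * f[3] + f[1] * f[2]
        phase = 0.5 if denom == 0 else f[0] * f[3] / denom
        cAB = 2 * n[2, 2] + n[2, 1] + n[1, 2] + n_dh * phase
        cAb = 2 * n[2, 0] + n[2, 1] + n[1, 0] + n_dh * (1 - phase)
        caB = 2 * n[0, 2] + n[0, 1] + n[1, 2] + n_dh * (1 - phase)
        cab = 2 * n[0, 0] + n[0, 1] + n[1, 0] + n_dh * phase
        new = np.array([cAB, cAb, caB, cab]) / n_hap
        delta = np.abs(new - f).max()
        f = new
        if delta < tol:
            break
    D = f[0] - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else D / d_max
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(tuple(f), float(D), float(d_prime), float(r2), it)


def _dosage_r2(G: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    X = G.astype(float).copy()
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    r = X.T @ X / X.shape[0]
    return r * r


def ld_prune(G: np.ndarray, r2_max: float = 0.1, window: int = 50,
             step: int = 5) -> list[int]:
    """Sliding-window greedy LD pruning; returns kept column indices.

    Within each window, while any kept pair has dosage r^2 > ``r2_max``,
    the member with the lower MAF is dropped (tie: higher index). After
    the pass no remaining within-window pair exceeds the threshold.
    """
    m = G.shape[1]
    af = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        if len(idx) > 1:
            r2 = _dosage_r2(G[:, idx])
            active = list(range(len(idx)))
            changed = True
            while changed:
                changed = False
                for ii in range(len(active)):
                    for jj in range(ii + 1, len(active)):
                        a, b = active[ii], active[jj]
                        if r2[a, b] > r2_max:
                            ja, jb = idx[a], idx[b]
                            drop = jb if (maf[jb] < maf[ja]) or (maf[jb] == maf[ja]) else ja
                            keep[drop] = False
                            active.remove(a if drop == ja else b)
                            changed = True
                            break
                    if changed:
                        break
        if start + window >= m:
            break
        start += step
    return [j for j in range(m) if keep[j]]


@dataclass
class PCAResult:
    scores: np.ndarray        # samples x K
    loadings: np.ndarray      # kept sites x K
    var_explained: np.ndarray
    kept_sites: list[int]


def pca(G: np.ndarray, maf_min: float = 0.01, hwe_alpha: float | None = None,
        K: int = 10, prune_r2: float | None = 0.1, window: int = 50,
        step: int = 5) -> PCAResult:
    """Genotype PCA with MAF / HWE / LD-pruning site filters.

    ``hwe_alpha`` defaults to the Bonferroni level 0.05 / (number of
    MAF-passing sites). Missing dosages are mean-imputed after centering.
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """
    n, m = G.shape
    af = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    cand = [j for j in range(m) if maf[j] > maf_min]
    if hwe_alpha is None:
        hwe_alpha = 0.05 / max(len(cand), 1)
    kept = []
    for j in cand:
        col = G[:, j]
        counts = (int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))
        if hwe_exact(*counts) > hwe_alpha:
            kept.append(j)
    if prune_r2 is not None and len(kept) > 1:
        sub = ld_prune(G[:, kept], r2_max=prune_r2, window=window, step=step)
        kept = [kept[j] for j in sub]
    if not kept or n < K + 1:
        raise ValueError("no sites (or too few samples) survive the PCA filters")
    X = G[:, kept].astype(float).copy()
    p = np.nanmean(X, axis=0) / 2.0
    X -= 2 * p
    X[np.isnan(X)] = 0.0
    X /= np.sqrt(2 * p * (1 - p))
    K = min(K, min(X.shape) - 1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s ** 2).sum())
    scores = U[:, :K] * s[:K]
    loadings = Vt[:K].T
    for k in range(K):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    return PCAResult(scores=scores, loadings=loadings,
                     var_explained=(s[:K] ** 2) / total, kept_sites=kept)


def pc_batch_screen(scores: np.ndarray, batches: Sequence[str]) -> pd.DataFrame:
    """Per-PC Kruskal-Wallis test across batch labels + separation flag.

    ``complete_separation`` is true when the score ranges of two batches
    are disjoint — the signature of a PC that encodes a technical batch
    rather than ancestry.
    """
    batches = np.asarray(batches)
    levels = sorted(set(batches))
    if len(levels) < 2:
        raise ValueError("need at least two batch levels")
    rows = []
    for k in range(scores.shape[1]):
        groups = [scores[batches == b, k] for b in levels]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            p = 1.0
        else:
            p = float(stats.kruskal(*groups).pvalue)
        sep = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i].max() < groups[j].min() or groups[j].max() < groups[i].min():
                    sep = True
        rows.append({"pc": k + 1, "p": p, "complete_separation": sep})
    return pd.DataFrame(rows)
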