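"""Gene-based rare-variant set tests: burden, SKAT, and the hybrid combination.

Rare (MAF < 1%) pathogenic SVs are aggregated per gene — alone in the
primary analysis, or pooled with functional categories of rare SNVs/INDELs
in the secondary analysis. Each set is tested with score-based statistics
under a single null logistic model of disease on covariates:

* burden — score test of the weighted dosage sum (powerful when effects
  share a direction),
* SKAT — a variance-component statistic, the weighted sum of squared
  per-variant scores, whose null is a mixture of chi-squares evaluated by
  moment matching on the eigenvalues of the projected genotype covariance,
* hybrid — the burden test combined with SKAT on burden-orthogonalized
  genotypes via Fisher's method (4 df), capturing both shared-direction
  and heterogeneous effects.

Sets with a cumulative minor allele count below 10 are not tested.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from svcohort.annotate import GeneModels
from svcohort.assoc_single import _logistic_fit
from svcohort.sv_model import SVRecord, SVType

logger = logging.getLogger(__name__)

CODING_CATEGORIES = frozenset({
    "pLoF", "missense", "disruptive_missense", "pLoF_plus_disruptive", "synonymous",
})
NONCODING_CATEGORIES = frozenset({
    "promoter_cage", "enhancer_cage", "promoter_dhs", "enhancer_dhs",
    "utr", "upstream", "downstream", "ncRNA",
})
GENOME_WIDE_P = 1e-7   # ~20,000 genes Bonferroni
SUGGESTIVE_P = 1e-5


@dataclass(frozen=True)
class PathogenicityCall:
    sv_id: str
    gene_id: str
    score: float
    is_coding: bool

    @property
    def is_pathogenic(self) -> bool:
        return self.score >= 0.5


@dataclass
class SetMember:
    variant_id: str
    dosage: np.ndarray
    maf: float
    weight: float = 1.0
    is_sv: bool = False


@dataclass
class VariantSet:
    gene_id: str
    category: str
    members: list[SetMember]

    @property
    def cmac(self) -> int:
        return int(sum(np.nansum(m.dosage) for m in self.members))

    def genotype_matrix(self) -> np.ndarray:
        G = np.column_stack([m.dosage for m in self.members]).astype(float)
        return np.nan_to_num(G, nan=0.0)

    def weights(self) -> np.ndarray:
        return np.array([m.weight for m in self.members], dtype=float)


def classify_sv(sv: SVRecord, models: GeneModels,
                score_table: Mapping[tuple[str, str], float],
                noncoding_window: int = 1_000_000) -> list[PathogenicityCall]:
    """Per-(SV, gene) pathogenicity calls from a precomputed score table.

    An SV is coding for a gene when it overlaps >= 1 bp of that gene's
    representative-transcript exons; non-coding SVs are evaluated against
    all genes within 1 Mb. SVs absent from the score table are benign
    (score 0) with a warning.
    """
    if sv.svtype == SVType.INS:
        qs, qe = sv.start, sv.start + 1
    else:
        qs, qe = sv.start, sv.end
    exon_genes = {f.gene_id for f in models.overlapping_features(sv.chrom, qs, qe)
                  if f.feature in ("exon", "cds")}
    if exon_genes:
        genes, coding = sorted(exon_genes), True
    else:
        genes = sorted(models.overlapping_genes(sv.chrom, qs - noncoding_window,
                                                qe + noncoding_window))
        coding = False
    calls = []
    for g in genes:
        score = score_table.get((sv.record_id, g))
        if score is None:
            logger.warning("SV %s gene %s missing from score table; treated as benign",
                           sv.record_id, g)
            score = 0.0
        calls.append(PathogenicityCall(sv.record_id, g, float(score), coding))
    return calls


def variant_weight(maf: float, mode: str = "beta:1,25") -> float:
    """Per-variant weight from MAF: Beta(1, 25) density (default) or MAF itself."""
    if mode == "maf":
        return maf
    if mode.startswith("beta:"):
        a, b = (float(x) for x in mode[5:].split(","))
        return float(stats.beta.pdf(maf, a, b))
    raise ValueError(f"unknown weight mode {mode!r}")


def build_sets(snv_members: Sequence[tuple[str, str, SetMember]],
               sv_members: Sequence[tuple[PathogenicityCall, SetMember]],
               mode: str = "sv_only", maf_max: float = 0.01,
               cmac_min: int = 10, weight_mode: str = "beta:1,25",
               ) -> list[VariantSet]:
    """Assemble per-(gene, category) rare-variant sets.

    ``snv_members`` are (gene_id, category, member) tuples; ``sv_members``
    pair a pathogenicity call with the SV's dosage member. Only pathogenic
    SVs and members with MAF < ``maf_max`` enter; sets below ``cmac_min``
    are dropped. ``mode='sv_only'`` builds per-gene coding/non-coding SV
    sets (primary analysis); ``mode='combined'`` appends matching-type SVs
    to each SNV category (secondary analysis).
    """
    groups: dict[tuple[str, str], list[SetMember]] = {}
    sv_by_gene: dict[tuple[str, bool], list[SetMember]] = {}
    for call, member in sv_members:
        if not call.is_pathogenic or not (member.maf < maf_max):
            continue
        member.is_sv = True
        member.weight = variant_weight(member.maf, weight_mode)
        sv_by_gene.setdefault((call.gene_id, call.is_coding), []).append(member)
    if mode == "sv_only":
        for (gene, coding), members in sv_by_gene.items():
            cat = "sv_coding" if coding else "sv_noncoding"
            groups[(gene, cat)] = list(members)
    elif mode == "combined":
        for gene, cat, member in snv_members:
            if not (member.maf < maf_max):
                continue
            member.weight = variant_weight(member.maf, weight_mode)
            groups.setdefault((gene, cat), []).append(member)
        for (gene, cat) in list(groups):
            coding = cat in CODING_CATEGORIES
            for sv in sv_by_gene.get((gene, coding), []):
                groups[(gene, cat)].append(sv)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for (gene, cat) in sorted(groups):
        vs = VariantSet(gene, cat, groups[(gene, cat)])
        if vs.cmac >= cmac_min:
            out.append(vs)
    return out


class NullModel:
    """Null logistic fit y ~ X shared by all set tests of one phenotype."""

    def __init__(self, y: Sequence[int], X: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        beta, _, _ = _logistic_fit(self.y, self.X)
        mu = 1.0 / (1.0 + np.exp(-np.clip(self.X @ beta, -30, 30)))
        self.mu = mu
        self.resid = self.y - mu
        self.W = mu * (1 - mu)
        self.XtWX_inv = np.linalg.pinv(self.X.T @ (self.X * self.W[:, None]))

    def proj_cov(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Covariance of score vectors A'(y-mu), B'(y-mu) under the null:
        A' P B with P = W - W X (X'WX)^-1 X' W."""
        AW = A * self.W[:, None]
        return A.T @ (B * self.W[:, None]) - (AW.T @ self.X) @ self.XtWX_inv @ (self.X.T @ (B * self.W[:, None]))


def burden_test(vset: VariantSet, null: NullModel) -> tuple[float, float]:
    """Score test of the weighted dosage sum; returns (statistic, p)."""
    G = vset.genotype_matrix()
    b = G @ vset.weights()
    if np.ptp(b) == 0:
        return 0.0, 1.0
    U = float(b @ null.resid)
    V = float(null.proj_cov(b[:, None], b[:, None])[0, 0])
    if V <= 0:
        return 0.0, 1.0
    stat = U * U / V
    return stat, float(stats.chi2.sf(stat, 1))


def liu_sf(q: float, lambdas: np.ndarray) -> float:
    """Tail probability of sum(lambda_k chi2_1) by Liu-type moment matching."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    c = np.array([np.sum(lam ** k) for k in (1, 2, 3, 4)])
    s1 = c[2] / c[1] ** 1.5
    s2 = c[3] / c[1] ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1 ** 2 - s2))
        d = s1 * a ** 3 - a ** 2
        l = a ** 2 - 2 * d
    else:
        l = 1.0 / s2
        a = math.sqrt(l)
        d = 0.0
    mu_q, sigma_q = c[0], math.sqrt(2 * c[1])
    t = (q - mu_q) / sigma_q * math.sqrt(2) * a + l + d
    if d > 0:
        return float(stats.ncx2.sf(t, l, d))
    return float(stats.chi2.sf(t, l))


def skat_test(vset: VariantSet, null: NullModel,
              G_override: np.ndarray | None = None) -> tuple[float, float]:
    """Variance-component score test; returns (Q, p).

    Q sums the squared weighted per-variant scores; its null distribution is
    the chi-square mixture with weights equal to the eigenvalues of the
    projected weighted-genotype covariance.
    """
    if G_override is not None:
        Gw = G_override
    else:
        Gw = vset.genotype_matrix() * vset.weights()
    scores = Gw.T @ null.resid
    Q = float(scores @ scores)
    Sigma = null.proj_cov(Gw, Gw)
    lam = np.linalg.eigvalsh((Sigma + Sigma.T) / 2)
    lam = np.clip(lam, 0, None)
    if lam.max(initial=0.0) <= 1e-12:
        return Q, 1.0
    return Q, liu_sf(Q, lam)


def smmat_e(vset: VariantSet, null: NullModel) -> float:
    """Hybrid burden + adjusted-SKAT p-value.

    The SKAT component runs on genotypes orthogonalized against the burden
    direction (in the null-model metric), making the two score statistics
    asymptotically independent; the p-values combine by Fisher's method
    (chi-square, 4 df).
    """
    _, p_burden = burden_test(vset, null)
    Gw = vset.genotype_matrix() * vset.weights()
    b = Gw.sum(axis=1)
    bPb = float(null.proj_cov(b[:, None], b[:, None])[0, 0])
    if bPb <= 0:
        return p_burden
    coef = null.proj_cov(b[:, None], Gw)[0] / bPb
    G_res = Gw - np.outer(b, coef)
    _, p_adj = skat_test(vset, null, G_override=G_res)
    x = -2.0 * (math.log(max(p_burden, 5e-324)) + math.log(max(p_adj, 5e-324)))
    return float(stats.chi2.sf(x, 4))


def conditional_set_test(set_sv_only: VariantSet, set_snv_only: VariantSet,
                         y: Sequence[int], X: np.ndarray) -> float:
    """Hybrid test of the SV members with the SNV burden as a covariate."""
    if not set_sv_only.members or not set_snv_only.members:
        raise ValueError("both sets must be nonempty")
    snv_burden = set_snv_only.genotype_matrix() @ set_snv_only.weights()
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(np.column_stack([X, snv_burden])) <= np.linalg.matrix_rank(X):
        raise ValueError("SNV burden is collinear with the covariates")
    null = NullModel(y, np.column_stack([X, snv_burden]))
    return smmat_e(set_sv_only, null)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def meta_gene(pvals: Sequence[float], n_samples: Sequence[float]) -> float:
    """Sample-size-weighted one-sided Stouffer combination of set p-values."""
    p = np.asarray(pvals, dtype=float)
    n = np.asarray(n_samples, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least two groups")
    eps = 1e-300
    if np.any(p <= 0) or np.any(p >= 1):
        warnings.warn("p-values clipped to machine bounds")
        p = np.clip(p, eps, 1 - 1e-16)
    z = stats.norm.isf(p)
    z_meta = float((np.sqrt(n) * z).sum() / math.sqrt(n.sum()))
    return float(stats.norm.sf(z_meta))
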