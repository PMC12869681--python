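"""Sample-level QC, cohort genotype-matrix construction, and site summaries.

Sample filtering happens in two stages: individual samples whose per-type SV
counts are multivariate outliers are flagged (a fixed 2% of the cohort by
robust Mahalanobis distance), and studies in which flagged samples
concentrate beyond binomial expectation are dropped wholesale. The
remaining per-sample callsets are collapsed into cohort sites with a
samples x sites dosage matrix, from which allele frequencies, the site
frequency spectrum, singleton rates, and Hardy-Weinberg exact tests are
computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from svcohort.sv_compare import MatchParams, collapse
from svcohort.sv_model import Genotype, SampleMeta, SVRecord, SVType

logger = logging.getLogger(__name__)

SIZE_BIN_EDGES = [50, 100, 300, 1000, 2500, 5000, math.inf]
SIZE_BIN_LABELS = ["50-100", "100-300", "300-1000", "1000-2500", "2500-5000", ">5000"]
AF_BIN_EDGES = [0.0, 0.001, 0.01, 0.1, 0.5, 1.0]
AF_BIN_LABELS = ["<0.1%", "0.1-1%", "1-10%", "10-50%", ">=50%"]


@dataclass(frozen=True)
class SampleCounts:
    sample_id: str
    n_del: int
    n_ins: int
    n_inv: int


def count_by_type(records_by_sample: Mapping[str, Sequence[SVRecord]]) -> list[SampleCounts]:
    out = []
    for sid in sorted(records_by_sample):
        recs = records_by_sample[sid]
        out.append(SampleCounts(
            sample_id=sid,
            n_del=sum(r.svtype == SVType.DEL for r in recs),
            n_ins=sum(r.svtype == SVType.INS for r in recs),
            n_inv=sum(r.svtype == SVType.INV for r in recs),
        ))
    return out


def detect_outlier_samples(counts: Sequence[SampleCounts],
                           fraction: float = 0.02) -> list[str]:
    """Flag the most extreme ``fraction`` of samples by per-type SV counts.

    Counts are log1p-transformed; a robust Mahalanobis distance is computed
    from the coordinate-wise median and a rank-based covariance (Spearman
    correlation rescaled by MAD), and the ceil(fraction * n) largest
    distances are flagged. Deterministic; ties resolved by sample id.
    """
    n = len(counts)
    if n < 50:
        raise ValueError("need at least 50 samples for a stable covariance")
    if fraction <= 0:
        return []
    ids = [c.sample_id for c in counts]
    x = np.log1p(np.array([[c.n_del, c.n_ins, c.n_inv] for c in counts], dtype=float))
    center = np.median(x, axis=0)
    mad = np.median(np.abs(x - center), axis=0)
    scale = np.where(mad > 0, 1.4826 * mad, 1.0)
    ranks = stats.rankdata(x, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.nan_to_num(np.asarray(rho), nan=0.0)  # constant columns -> 0
    np.fill_diagonal(rho, 1.0)
    corr = 2.0 * np.sin(np.pi / 6.0 * rho)  # Spearman -> Pearson under normality
    cov = corr * np.outer(scale, scale)
    prec = np.linalg.pinv(cov, hermitian=True)
    d = x - center
    dist2 = np.einsum("ij,jk,ik->i", d, prec, d)
    k = math.ceil(fraction * n)
    order = sorted(range(n), key=lambda i: (-dist2[i], ids[i]))
    return sorted(ids[i] for i in order[:k])


def flag_outlier_studies(flagged: Sequence[str], meta: Sequence[SampleMeta],
                         alpha: float = 0.05, min_outliers: int = 2) -> list[str]:
    """Studies where flagged samples concentrate beyond binomial expectation.

    One-sided binomial test of each study's outlier count against the
    global outlier rate, BH-adjusted; a study is returned when q < alpha
    and it contains at least ``min_outliers`` flagged samples. All samples
    of returned studies are dropped downstream.
    """
    by_study: dict[str, int] = {}
    flagged_set = set(flagged)
    n_flag_by_study: dict[str, int] = {}
    for m in meta:
        by_study[m.study] = by_study.get(m.study, 0) + 1
        if m.sample_id in flagged_set:
            n_flag_by_study[m.study] = n_flag_by_study.get(m.study, 0) + 1
    n_total = len(meta)
    rate = len(flagged_set) / n_total if n_total else 0.0
    if rate == 0:
        return []
    studies = sorted(by_study)
    pvals = [stats.binomtest(n_flag_by_study.get(s, 0), by_study[s], rate,
                             alternative="greater").pvalue for s in studies]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [s for s, q in zip(studies, qvals)
            if q < alpha and n_flag_by_study.get(s, 0) >= min_outliers]


@dataclass
class CohortCallset:
    """Collapsed cohort sites with a samples x sites dosage matrix."""

    sites: list[SVRecord]
    samples: list[SampleMeta]
    dosage: np.ndarray  # float, NaN for missing genotypes
    cluster_map: dict[str, str] = field(default_factory=dict)

    @property
    def site_ids(self) -> list[str]:
        return [s.record_id for s in self.sites]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ac(self) -> np.ndarray:
        return np.nansum(self.dosage, axis=0).astype(int)

    @property
    def an(self) -> np.ndarray:
        return 2 * np.sum(~np.isnan(self.dosage), axis=0)

    @property
    def af(self) -> np.ndarray:
        an = self.an
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, self.ac / an, np.nan)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        col = self.dosage[:, j]
        return (int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))

    def subset_samples(self, keep: Sequence[str]) -> "CohortCallset":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.samples) if s.sample_id in keep_set]
        return CohortCallset(self.sites, [self.samples[i] for i in idx],
                             self.dosage[idx, :], self.cluster_map)


def build_cohort(records_by_sample: Mapping[str, Sequence[SVRecord]],
                 meta: Sequence[SampleMeta],
                 match_params: MatchParams = MatchParams(),
                 read_length: int | None = None) -> CohortCallset:
    """Collapse per-sample callsets into a cohort genotype matrix.

    Sites are defined by :func:`svcohort.sv_compare.collapse` over the pooled
    record list; each sample's genotype at a site comes from its member
    record (absent -> hom-ref dosage 0). With ``read_length`` set, only
    samples with that metadata read length enter the matrix.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    kept = [m for m in meta if m.sample_id in records_by_sample
            and (read_length is None or m.read_length == read_length)]
    pooled: list[SVRecord] = []
    for m in kept:
        pooled.extend(records_by_sample[m.sample_id])
    pooled.sort(key=lambda r: (r.chrom, r.start, r.record_id))
    sites, cluster_map = collapse(pooled, match_params)
    site_index = {s.record_id: j for j, s in enumerate(sites)}
    sample_index = {m.sample_id: i for i, m in enumerate(kept)}
    dosage = np.zeros((len(kept), len(sites)))
    best_qual = np.full((len(kept), len(sites)), -np.inf)
    for r in pooled:
        i = sample_index[r.sample_id]
        j = site_index[cluster_map[r.record_id]]
        if best_qual[i, j] > -np.inf:
            logger.warning("sample %s has multiple records in site %s; keeping higher qual",
                           r.sample_id, sites[j].record_id)
            if r.qual <= best_qual[i, j]:
                continue
        best_qual[i, j] = r.qual
        dosage[i, j] = r.dosage
    return CohortCallset(sites=sites, samples=kept, dosage=dosage, cluster_map=cluster_map)


def type_composition(callset_or_counts) -> dict[str, float]:
    """Percentage of sites per SV type (values on the 0-100 scale)."""
    if isinstance(callset_or_counts, Mapping):
        counts = {str(k): int(v) for k, v in callset_or_counts.items()}
    else:
        counts = {}
        for s in callset_or_counts.sites:
            counts[s.svtype.value] = counts.get(s.svtype.value, 0) + 1
    total = sum(counts.values())
    return {k: 100.0 * v / total for k, v in sorted(counts.items())}


def size_bin(svlen: int) -> str:
    """Left-closed, right-open size bins: [50,100), [100,300), ... , >5000."""
    for lo, hi, lab in zip(SIZE_BIN_EDGES[:-1], SIZE_BIN_EDGES[1:], SIZE_BIN_LABELS):
        if lo <= svlen < hi:
            return lab
    return SIZE_BIN_LABELS[0]


def sfs_summary(callset: CohortCallset) -> dict[str, pd.DataFrame | pd.Series | float]:
    """Site-frequency-spectrum style summaries of a collapsed callset.

    Returns AF-bin counts per type, singleton proportion per type and per
    size bin (singleton = allele count 1), and the fraction of sites with
    AF below 1%.
    """
    if len(callset.sites) == 0:
        raise ValueError("empty callset")
    df = pd.DataFrame({
        "svtype": [s.svtype.value for s in callset.sites],
        "svlen": [s.svlen for s in callset.sites],
        "af": callset.af,
        "ac": callset.ac,
    })
    df["size_bin"] = pd.Categorical([size_bin(l) for l in df["svlen"]],
                                    categories=SIZE_BIN_LABELS)
    df["af_bin"] = pd.cut(df["af"], AF_BIN_EDGES, labels=AF_BIN_LABELS,
                          right=False, include_lowest=True)
    # AF exactly 1.0 falls in the top bin despite right=False
    df.loc[df["af"] >= AF_BIN_EDGES[-2], "af_bin"] = AF_BIN_LABELS[-1]
    df["singleton"] = df["ac"] == 1
    af_bins = df.groupby(["svtype", "af_bin"], observed=False).size().unstack(fill_value=0)
    singleton_by_type = df.groupby("svtype")["singleton"].mean()
    singleton_by_size = df.groupby(["svtype", "size_bin"], observed=False)["singleton"].mean().unstack()
    return {
        "af_bins": af_bins,
        "singleton_by_type": singleton_by_type,
        "singleton_by_size": singleton_by_size,
        "frac_af_lt_1pct": float((df["af"] < 0.01).mean()),
        "table": df,
    }


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditional on the observed allele count, heterozygote counts follow a
    hypergeometric-type null; the p-value sums the probabilities of all
    heterozygote configurations no more probable than the observed one.
    Monomorphic sites return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    logp = (hets * math.log(2.0)
            + gammaln(n + 1) - gammaln(hets + 1) - gammaln(rare_homs + 1)
            - gammaln(common_homs + 1)
            + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
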