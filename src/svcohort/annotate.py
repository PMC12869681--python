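"""Known-SV catalog intersection and gene-model annotation.

Novelty is decided by matching cohort sites against external SV catalogs:
deletions/inversions by same-type reciprocal overlap, insertions by anchor
distance plus size similarity (catalog insertion lengths are approximate).
Allele-frequency concordance of the matched common sites (squared Pearson
correlation) serves as a call-set accuracy check.

Gene annotation classifies every site as overlapping a gene body, proximal
(within 5 kbp), or intergenic. Deletions and inversions are annotated by
their full reference span; insertions by the single anchor base only, since
an insertion disturbs just the junction where it lands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from svcohort.cohort_qc import CohortCallset
from svcohort.sv_compare import size_similarity
from svcohort.sv_model import SVRecord, SVType

GENE_FEATURES = ("cds", "utr5", "utr3", "exon", "intron")
FEATURE_PRIORITY = {f: i for i, f in enumerate(("cds", "utr5", "utr3", "exon", "intron"))}


@dataclass(frozen=True)
class CatalogEntry:
    source: str
    chrom: str
    start: int
    end: int
    svtype: SVType
    af: float | None = None
    svlen: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("catalog entry needs start < end")
        if self.af is not None and not (0 <= self.af <= 1):
            raise ValueError("catalog AF must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.svlen if self.svlen is not None else self.end - self.start


def read_catalog_bed(path: str | Path, source: str | None = None) -> list[CatalogEntry]:
    """Read a BED-like catalog: chrom, start, end, svtype[, af[, svlen]]."""
    path = Path(path)
    source = source or path.stem
    entries = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for row in df.itertuples(index=False):
        af = float(row[4]) if len(row) > 4 and not pd.isna(row[4]) else None
        svlen = int(row[5]) if len(row) > 5 and not pd.isna(row[5]) else None
        entries.append(CatalogEntry(source, str(row[0]), int(row[1]), int(row[2]),
                                    SVType(str(row[3])), af, svlen))
    return entries


@dataclass(frozen=True)
class GeneFeature:
    chrom: str
    start: int
    end: int
    gene_id: str
    feature: str  # one of GENE_FEATURES


@dataclass
class GeneModels:
    """Representative-transcript gene models as flat feature intervals."""

    genes: dict[str, tuple[str, int, int]]  # gene_id -> (chrom, start, end)
    features: list[GeneFeature]

    def __post_init__(self) -> None:
        self._span_trees: dict[str, IntervalTree] = {}
        for gid, (chrom, s, e) in self.genes.items():
            self._span_trees.setdefault(chrom, IntervalTree()).addi(s, e, gid)
        self._feat_trees: dict[str, IntervalTree] = {}
        for f in self.features:
            self._feat_trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._span_trees.get(chrom)
        return {iv.data for iv in tree.overlap(start, end)} if tree else set()

    def overlapping_features(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        tree = self._feat_trees.get(chrom)
        return sorted((iv.data for iv in tree.overlap(start, end)) if tree else [],
                      key=lambda f: (f.gene_id, f.start, f.feature))

    def nearest_gene_distance(self, chrom: str, start: int, end: int) -> tuple[str | None, int]:
        best_gene, best_d = None, math.inf
        tree = self._span_trees.get(chrom)
        if tree is None:
            return None, math.inf
        for iv in tree:
            if iv.end <= start:
                d = start - iv.end + 1
            elif iv.begin >= end:
                d = iv.begin - end + 1
            else:
                return iv.data, 0
            if d < best_d or (d == best_d and (best_gene is None or iv.data < best_gene)):
                best_gene, best_d = iv.data, d
        return best_gene, best_d


_GFF_FEATURE_MAP = {
    "CDS": "cds", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3",
    "exon": "exon", "intron": "intron",
}


def read_gene_models_gff3(path: str | Path) -> GeneModels:
    """Load gene models from GFF3, one representative transcript per gene.

    Recognized feature types: gene, exon, CDS, five_prime_UTR,
    three_prime_UTR (introns derived as gene-span gaps between exons).
    Gene identity comes from the ID= (gene) / Parent= (features) attribute.
    """
    genes: dict[str, tuple[str, int, int]] = {}
    raw: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line[:80]!r}")
            chrom, _, ftype, start, end, _, _, _, attrs = cols[:9]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start) - 1, int(end)  # GFF3 is 1-based inclusive
            if ftype == "gene":
                gid = attr.get("ID", attr.get("gene_id", f"{chrom}:{s}"))
                genes[gid] = (chrom, s, e)
            elif ftype in _GFF_FEATURE_MAP:
                gid = attr.get("gene_id") or attr.get("Parent", "").split(":")[0]
                raw.setdefault(gid, []).append((chrom, s, e, _GFF_FEATURE_MAP[ftype]))
    features: list[GeneFeature] = []
    for gid, (chrom, gs, ge) in genes.items():
        feats = raw.get(gid, [])
        for c, s, e, f in feats:
            features.append(GeneFeature(c, s, e, gid, f))
        exons = sorted((s, e) for c, s, e, f in feats if f == "exon")
        prev = gs
        for s, e in exons:  # gaps between exons inside the gene span
            if s > prev:
                features.append(GeneFeature(chrom, prev, s, gid, "intron"))
            prev = max(prev, e)
        if exons and prev < ge:
            features.append(GeneFeature(chrom, prev, ge, gid, "intron"))
    return GeneModels(genes=genes, features=features)


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def intersect_catalog(callset: CohortCallset, catalogs: Sequence[CatalogEntry],
                      del_inv_recip_overlap: float = 0.5,
                      ins_max_dist: int = 1000,
                      ins_size_sim: float = 0.5) -> pd.DataFrame:
    """Match cohort sites against known-SV catalogs; returns one row per site.

    DEL/INV match by same-type reciprocal overlap >= threshold; INS by
    anchor distance <= ``ins_max_dist`` and size similarity >=
    ``ins_size_sim``. A site is *known* when matched in at least one
    catalog; ``matched_af`` reports the best match's catalog AF.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for e in catalogs:
        key = (e.chrom, e.svtype.value)
        pad = ins_max_dist if e.svtype == SVType.INS else 0
        trees.setdefault(key, IntervalTree()).addi(e.start - pad, e.end + pad, e)
    rows = []
    for j, site in enumerate(callset.sites):
        tree = trees.get((site.chrom, site.svtype.value), IntervalTree())
        best: tuple[float, CatalogEntry] | None = None
        sources: set[str] = set()
        for iv in tree.overlap(site.start, site.end):
            e: CatalogEntry = iv.data
            if site.svtype == SVType.INS:
                dist = abs(site.start - e.start)
                if dist > ins_max_dist:
                    continue
                if size_similarity(site.svlen, max(e.length, 1)) < ins_size_sim:
                    continue
                score = 1.0 - dist / (ins_max_dist + 1)
            else:
                score = reciprocal_overlap(site.start, site.end, e.start, e.end)
                if score < del_inv_recip_overlap:
                    continue
            sources.add(e.source)
            if best is None or score > best[0]:
                best = (score, e)
        rows.append({
            "site_id": site.record_id,
            "svtype": site.svtype.value,
            "cohort_af": callset.af[j],
            "known": best is not None,
            "sources": ",".join(sorted(sources)),
            "matched_af": best[1].af if best is not None else np.nan,
            "match_score": best[0] if best is not None else np.nan,
        })
    return pd.DataFrame(rows)


def af_concordance(matched: pd.DataFrame, min_af: float = 0.01) -> tuple[float, float]:
    """Squared Pearson correlation of cohort vs catalog AF on common sites.

    Restricted to matched sites with cohort AF >= ``min_af`` and a catalog
    AF present. Returns (r^2, two-sided p for zero correlation).
    """
    sub = matched[(matched["known"]) & (matched["cohort_af"] >= min_af)
                  & matched["matched_af"].notna()]
    if len(sub) < 3:
        raise ValueError("need at least 3 matched common sites")
    r, p = stats.pearsonr(sub["cohort_af"], sub["matched_af"])
    return float(r * r), float(p)


@dataclass
class GeneAnnotation:
    site_id: str
    klass: str  # gene_overlap / proximal_5kb / intergenic
    features: frozenset[str]
    gene_ids: tuple[str, ...]


def annotate_genes(callset: CohortCallset, models: GeneModels,
                   proximity: int = 5000) -> list[GeneAnnotation]:
    """Classify each site against the gene models.

    DEL/INV use their full reference span; INS the single anchor base.
    Classes are mutually exclusive: gene_overlap (any gene-span overlap),
    proximal_5kb (nearest gene within ``proximity`` bp, no overlap), else
    intergenic.
    """
    out = []
    for site in callset.sites:
        if site.svtype == SVType.INS:
            qs, qe = site.start, site.start + 1
        else:
            qs, qe = site.start, site.end
        genes = models.overlapping_genes(site.chrom, qs, qe)
        if genes:
            feats = frozenset(f.feature for f in models.overlapping_features(site.chrom, qs, qe))
            out.append(GeneAnnotation(site.record_id, "gene_overlap", feats,
                                      tuple(sorted(genes))))
            continue
        gene, d = models.nearest_gene_distance(site.chrom, qs, qe)
        if gene is not None and d <= proximity:
            out.append(GeneAnnotation(site.record_id, "proximal_5kb", frozenset(), (gene,)))
        else:
            out.append(GeneAnnotation(site.record_id, "intergenic", frozenset(), ()))
    return out


def candidate_gene_report(callset: CohortCallset, annotations: Sequence[GeneAnnotation],
                          gene_list: Sequence[str], min_af: float = 0.01,
                          exclude_intronic_only: bool = True) -> pd.DataFrame:
    """Common SVs hitting (non-intronic) gene bodies of candidate genes."""
    if not gene_list:
        raise ValueError("gene_list must be nonempty")
    gene_set = set(gene_list)
    ann_by_site = {a.site_id: a for a in annotations}
    rows = []
    for j, site in enumerate(callset.sites):
        af = callset.af[j]
        if not af >= min_af:
            continue
        a = ann_by_site.get(site.record_id)
        if a is None or a.klass != "gene_overlap":
            continue
        hit = gene_set & set(a.gene_ids)
        if not hit:
            continue
        if exclude_intronic_only and not (a.features - {"intron"}):
            continue
        for g in sorted(hit):
            rows.append({"gene": g, "site_id": site.record_id,
                         "svtype": site.svtype.value, "svlen": site.svlen, "af": af})
    return pd.DataFrame(rows, columns=["gene", "site_id", "svtype", "svlen", "af"])
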