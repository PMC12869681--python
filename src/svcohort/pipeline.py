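"""End-to-end pipeline: ingest -> replicate QC -> filters -> cohort -> annotation
-> PCA -> single-variant and gene-based association.

Every stage is a pure function of (inputs, config, seed); the manifest
records per-stage counts and SHA-256 hashes of each output file, so two
runs over the same bundle produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from svcohort import annotate as ann
from svcohort import assoc_gene as ag
from svcohort import assoc_single as asg
from svcohort import cohort_qc as cq
from svcohort import popstruct as ps
from svcohort import replicate_qc as rq
from svcohort import synthetic_data as sd
from svcohort.sv_compare import MatchParams
from svcohort.sv_model import parse_sv_vcf, write_sv_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's calibrated values
    (50 bp minimum length, PASS filter, 0.80 inversion similarity, 0.70
    replicate consistency, quality 50, 0.95/1000 bp collapse, 2% outliers,
    1% MAF for PCA, r2 0.1 pruning, 5 kbp proximity, 0.5% association MAF,
    r2 0.4 tag scan, 1% rare MAF, 0.5 pathogenicity, cMAC 10, and 1e-7 /
    1e-5 gene-based significance)."""

    input_dir: str
    out_dir: str
    seed: int = 0
    min_len: int = 50
    inv_sim_threshold: float = 0.80
    replicate_sim_min: float = 0.70
    calibrate_qual: bool = True
    qual_min: float = 50.0
    collapse_seq_sim: float = 0.95
    collapse_size_sim: float = 0.95
    collapse_max_dist: int = 1000
    outlier_fraction: float = 0.02
    read_length: int | None = None
    pca_maf_min: float = 0.01
    prune_r2: float = 0.1
    proximity: int = 5000
    assoc_maf_min: float = 0.005
    tag_r2_min: float = 0.4
    rare_maf_max: float = 0.01
    cmac_min: int = 10
    genomewide_p: float = 1e-7
    suggestive_p: float = 1e-5
    n_pcs: int = 5
    run_replicate_qc: bool = True
    run_annotation: bool = True
    run_assoc: bool = True
    run_gene_assoc: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _covariates(samples, scores: np.ndarray | None, n_pcs: int) -> np.ndarray:
    cols = [np.ones(len(samples))]
    cols.append(np.array([1.0 if m.sex == "M" else 0.0 for m in samples]))
    centers = sorted({m.center for m in samples})
    for c in centers[1:]:
        cols.append(np.array([1.0 if m.center == c else 0.0 for m in samples]))
    if scores is not None:
        for k in range(min(n_pcs, scores.shape[1])):
            cols.append(scores[:, k])
    X = np.column_stack(cols)
    # drop constant / duplicate covariate columns to keep the fit full rank
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            continue
        keep.append(j)
    return X[:, keep]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages over a fixture bundle; returns the manifest."""
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    # ---- ingest ------------------------------------------------------
    meta = sd.read_meta_tsv(indir / "meta.tsv")
    records_by_sample = {}
    for vcf in sorted((indir / "vcf").glob("*.vcf")):
        recs = parse_sv_vcf(vcf, min_len=cfg.min_len,
                            inv_sim_threshold=cfg.inv_sim_threshold)
        if recs:
            records_by_sample[recs[0].sample_id] = recs
        else:
            records_by_sample[vcf.stem] = recs
    n_raw = sum(len(v) for v in records_by_sample.values())
    manifest["stages"]["ingest"] = {"n_samples": len(records_by_sample), "n_records": n_raw}

    # ---- replicate QC + quality threshold ----------------------------
    qual_min = cfg.qual_min
    if cfg.run_replicate_qc:
        pairs = rq.replicate_pairs(meta)
        cons, incons = [], []
        n_cons = n_incons = 0
        for a_id, b_id in pairs:
            if a_id not in records_by_sample or b_id not in records_by_sample:
                continue
            rep = rq.classify_replicate_calls(records_by_sample[a_id],
                                              records_by_sample[b_id],
                                              sim_min=cfg.replicate_sim_min)
            cons.extend(rep.consistent_quals)
            incons.extend(rep.inconsistent_quals)
            n_cons += rep.n_consistent
            n_incons += rep.n_inconsistent
        if cfg.calibrate_qual and cons and incons:
            qual_min, j_stat = rq.calibrate_quality_threshold(cons, incons)
        else:
            j_stat = float("nan")
        manifest["stages"]["replicate_qc"] = {
            "n_pairs": len(pairs), "n_consistent": n_cons,
            "n_inconsistent": n_incons, "qual_threshold": qual_min,
            "youden_j": j_stat}

    # ---- quality filter ----------------------------------------------
    removed_total = 0
    for sid in sorted(records_by_sample):
        passed, removed = rq.apply_quality_filter(records_by_sample[sid], qual_min)
        records_by_sample[sid] = passed
        removed_total += removed
    n_passed = sum(len(v) for v in records_by_sample.values())
    assert n_raw == n_passed + removed_total
    manifest["stages"]["quality_filter"] = {
        "raw": n_raw, "removed": removed_total, "retained": n_passed,
        "threshold": qual_min}

    # ---- replicate reduction: keep the highest-call-count sample -----
    by_ind: dict[str, list] = {}
    for m in meta:
        by_ind.setdefault(m.individual_id, []).append(m)
    kept_meta = []
    for ind in sorted(by_ind):
        group = sorted(by_ind[ind],
                       key=lambda m: (-len(records_by_sample.get(m.sample_id, [])),
                                      m.sample_id))
        kept_meta.append(group[0])

    # ---- sample / study outlier QC -----------------------------------
    dropped_studies: list[str] = []
    flagged: list[str] = []
    if len(kept_meta) >= 50:
        counts = cq.count_by_type({m.sample_id: records_by_sample.get(m.sample_id, [])
                                   for m in kept_meta})
        flagged = cq.detect_outlier_samples(counts, cfg.outlier_fraction)
        dropped_studies = cq.flag_outlier_studies(flagged, kept_meta)
        kept_meta = [m for m in kept_meta if m.study not in dropped_studies]
    manifest["stages"]["sample_qc"] = {
        "n_flagged": len(flagged), "dropped_studies": dropped_studies,
        "n_samples_kept": len(kept_meta)}

    # ---- collapse + cohort matrix ------------------------------------
    params = MatchParams(cfg.collapse_seq_sim, cfg.collapse_size_sim,
                         cfg.collapse_max_dist)
    callset = cq.build_cohort({m.sample_id: records_by_sample[m.sample_id]
                               for m in kept_meta if m.sample_id in records_by_sample},
                              kept_meta, params, read_length=cfg.read_length)
    write_sv_vcf(callset.sites, outdir / "collapsed.vcf", sample_id="COHORT")
    dosage_df = pd.DataFrame(callset.dosage, index=callset.sample_ids,
                             columns=callset.site_ids)
    dosage_df.to_csv(outdir / "dosage.tsv", sep="\t")
    sfs = cq.sfs_summary(callset)
    sfs["af_bins"].to_csv(outdir / "sfs_af_bins.tsv", sep="\t")
    manifest["stages"]["cohort"] = {
        "n_sites": len(callset.sites), "n_samples": len(callset.samples),
        "composition_pct": cq.type_composition(callset),
        "frac_af_lt_1pct": sfs["frac_af_lt_1pct"]}

    # ---- annotation ---------------------------------------------------
    models = None
    annotations = None
    if cfg.run_annotation and (indir / "genes.gff3").exists():
        models = ann.read_gene_models_gff3(indir / "genes.gff3")
        annotations = ann.annotate_genes(callset, models, proximity=cfg.proximity)
        klass_counts = pd.Series([a.klass for a in annotations]).value_counts().to_dict()
        stage = {"class_counts": klass_counts}
        if (indir / "catalog.bed").exists():
            catalog = ann.read_catalog_bed(indir / "catalog.bed")
            matched = ann.intersect_catalog(callset, catalog)
            matched.to_csv(outdir / "catalog_match.tsv", sep="\t", index=False)
            stage["pct_known"] = float(100 * matched["known"].mean())
            try:
                r2, p = ann.af_concordance(matched)
                stage["af_concordance_r2"] = r2
            except ValueError:
                pass
        manifest["stages"]["annotate"] = stage

    # ---- PCA ----------------------------------------------------------
    scores = None
    try:
        pca_res = ps.pca(callset.dosage, maf_min=cfg.pca_maf_min,
                         prune_r2=cfg.prune_r2, K=max(cfg.n_pcs, 2))
        scores = pca_res.scores
        np.savetxt(outdir / "pca_scores.tsv", scores, delimiter="\t")
        manifest["stages"]["pca"] = {
            "n_sites_used": len(pca_res.kept_sites),
            "var_explained": [round(float(v), 6) for v in pca_res.var_explained]}
    except ValueError as exc:
        logger.warning("PCA skipped: %s", exc)
        manifest["stages"]["pca"] = {"skipped": str(exc)}

    # ---- single-variant association per ancestry + meta ---------------
    if cfg.run_assoc:
        rows = []
        ancestries = sorted({m.ancestry for m in callset.samples})
        per_site_group_results: dict[str, dict[str, asg.AssociationResult]] = {}
        for anc in ancestries:
            idx = [i for i, m in enumerate(callset.samples) if m.ancestry == anc]
            if len(idx) < 50:
                continue
            sub_samples = [callset.samples[i] for i in idx]
            y = np.array([1.0 if m.status == "case" else 0.0 for m in sub_samples])
            if y.min() == y.max():
                continue
            sub_scores = scores[idx] if scores is not None else None
            X = _covariates(sub_samples, sub_scores, cfg.n_pcs)
            D = callset.dosage[idx, :]
            af = np.nanmean(D, axis=0) / 2
            maf = np.minimum(af, 1 - af)
            testable = [j for j in range(D.shape[1]) if maf[j] > cfg.assoc_maf_min]
            hwe_alpha = asg.bonferroni_threshold(max(len(testable), 1))
            for j in testable:
                col = D[:, j]
                counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
                if cq.hwe_exact(*counts) <= hwe_alpha:
                    continue
                site_id = callset.site_ids[j]
                try:
                    res = asg.logistic_assoc(y, col, X, site_id=site_id,
                                             af_by_group={anc: float(af[j])})
                except ValueError:
                    continue
                per_site_group_results.setdefault(site_id, {})[anc] = res
                rows.append({"ancestry": anc, "site_id": site_id, "n": res.n,
                             "af": float(af[j]), "or": res.or_, "beta": res.beta,
                             "se": res.se, "z": res.z, "p": res.p,
                             "bonferroni": asg.bonferroni_threshold(len(testable))})
        for site_id, group in per_site_group_results.items():
            if len(group) >= 2:
                z_meta, p_meta = asg.stouffer_meta([r.z for r in group.values()],
                                                   [r.n for r in group.values()])
                rows.append({"ancestry": "META", "site_id": site_id,
                             "n": sum(r.n for r in group.values()),
                             "af": float("nan"), "or": float("nan"),
                             "beta": float("nan"), "se": float("nan"),
                             "z": z_meta, "p": p_meta, "bonferroni": float("nan")})
        assoc_df = pd.DataFrame(rows, columns=["ancestry", "site_id", "n", "af", "or",
                                               "beta", "se", "z", "p", "bonferroni"])
        assoc_df.to_csv(outdir / "assoc_single.tsv", sep="\t", index=False)
        manifest["stages"]["assoc_single"] = {
            "n_tests": int((assoc_df["ancestry"] != "META").sum()),
            "n_meta": int((assoc_df["ancestry"] == "META").sum())}

    # ---- gene-based rare-variant tests (SV-only primary) ---------------
    if cfg.run_gene_assoc and models is not None and (indir / "pathogenicity.tsv").exists():
        score_df = pd.read_csv(indir / "pathogenicity.tsv", sep="\t")
        by_pos: dict[str, dict[str, float]] = {}
        for r in score_df.itertuples(index=False):
            by_pos.setdefault(str(r.site_id), {})[str(r.gene_id)] = float(r.score)
        af = callset.af
        maf = np.minimum(af, 1 - af)
        y = np.array([1.0 if m.status == "case" else 0.0 for m in callset.samples])
        X = _covariates(callset.samples, scores, cfg.n_pcs)
        sv_members = []
        for j, site in enumerate(callset.sites):
            if not (maf[j] < cfg.rare_maf_max) or callset.ac[j] == 0:
                continue
            table = {(site.record_id, g): s
                     for g, s in by_pos.get(f"{site.chrom}:{site.start}", {}).items()}
            for call in ag.classify_sv(site, models, table):
                member = ag.SetMember(site.record_id,
                                      np.nan_to_num(callset.dosage[:, j]),
                                      float(maf[j]), is_sv=True)
                sv_members.append((call, member))
        sets = ag.build_sets([], sv_members, mode="sv_only",
                             maf_max=cfg.rare_maf_max, cmac_min=cfg.cmac_min)
        rows = []
        if sets and y.min() != y.max():
            null = ag.NullModel(y, X)
            for vs in sets:
                p = ag.smmat_e(vs, null)
                rows.append({"gene": vs.gene_id, "category": vs.category,
                             "n_variants": len(vs.members), "cmac": vs.cmac, "p": p})
        gene_df = pd.DataFrame(rows, columns=["gene", "category", "n_variants", "cmac", "p"])
        if len(gene_df):
            gene_df["q"] = ag.bh_fdr(gene_df["p"])
            gene_df["significant"] = gene_df["p"] < cfg.genomewide_p
            gene_df["suggestive"] = gene_df["p"] < cfg.suggestive_p
        gene_df.to_csv(outdir / "assoc_gene.tsv", sep="\t", index=False)
        manifest["stages"]["assoc_gene"] = {"n_sets": len(gene_df)}

    # ---- manifest ------------------------------------------------------
    manifest["outputs"] = {f.name: _sha256(f) for f in sorted(outdir.iterdir())
                           if f.is_file() and f.name != "manifest.json"}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
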