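"""Synthetic cohort generator with full ground truth.

Emulates the structure of a multi-ancestry short-read WGS SV study: per-
sample sequence-resolved SV calls over a synthetic reference, population
structure via the Balding-Nichols model, technical replicate pairs with
injected call errors, per-call quality scores drawn from separate true/false
mixtures, case-control phenotypes from a logistic model with configurable
per-site odds ratios, and a tag SNP placed in specified LD with an SV.

Every stochastic choice flows from ``SimConfig.seed``; the emitted truth
object records genotypes, causal effects, and per-call true/false labels so
each pipeline stage can be validated against what was planted.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from svcohort.annotate import CatalogEntry, GeneModels, GeneFeature
from svcohort.sv_model import (Genotype, SampleMeta, SVRecord, SVType,
                               reverse_complement, sv_length)

BASES = np.frombuffer(b"ACGT", dtype="S1")

ANCESTRIES = ("AFR", "EUR", "LAT")


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the emulated study's structure
    at desk scale (hundreds of samples / sites rather than thousands)."""

    seed: int = 0
    n_pops: int = 2
    n_per_pop: int = 150
    fst: float = 0.1
    n_sites: int = 300
    af_beta: tuple[float, float] = (0.3, 3.0)   # base allele-frequency law
    af_min: float = 0.002
    type_mix: tuple[float, float, float] = (0.5578, 0.4178, 0.0244)  # DEL/INS/INV
    size_log_scale: float = 1.0                 # 50 bp * exp(Exponential(scale))
    alu_fraction: float = 0.25                  # sites given the ~300 bp insertion mode
    size_max: int = 8000
    causal_effects: tuple[tuple[int, float], ...] = ()  # (site index, odds ratio)
    case_fraction: float = 0.47
    sex_log_or: float = 0.2
    center_log_or: float = 0.1
    replicate_individuals: int = 0
    replicate_dropout: float = 0.05
    breakpoint_jitter_sd: float = 3.0
    seq_error_rate: float = 0.002
    false_call_rate: float = 0.1                # expected false calls per true call
    qual_true: tuple[float, float] = (70.0, 10.0)   # Normal(mean, sd)
    qual_false: tuple[float, float] = (30.0, 10.0)
    n_studies: int = 6
    n_centers: int = 2
    read_length_alt_fraction: float = 0.0       # fraction of samples at 100 bp
    chrom_length: int = 1_500_000
    n_chroms: int = 2

    def __post_init__(self) -> None:
        for frac in (self.fst, self.case_fraction, self.replicate_dropout,
                     self.alu_fraction, self.read_length_alt_fraction):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction out of [0,1]: {frac}")
        if self.false_call_rate < 0 or self.seq_error_rate < 0:
            raise ValueError("rates must be nonnegative")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")
        for _, orr in self.causal_effects:
            if orr <= 0:
                raise ValueError("odds ratios must be positive")
        if self.causal_effects and max(s for s, _ in self.causal_effects) >= self.n_sites:
            raise ValueError("causal site index out of range")


@dataclass
class SiteDef:
    site_index: int
    chrom: str
    start: int
    svtype: SVType
    svlen: int
    ref_allele: str
    alt_allele: str

    @property
    def end(self) -> int:
        return self.start + len(self.ref_allele)


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated cohort."""

    genotypes: np.ndarray              # samples x sites, dosage 0/1/2
    sites: list[SiteDef]
    base_afs: np.ndarray
    pop_afs: np.ndarray                # pops x sites
    causal: dict[int, float]           # site index -> odds ratio
    case_status: np.ndarray            # bool per sample
    call_labels: dict[str, bool] = field(default_factory=dict)  # record_id -> is true call
    tag_info: dict = field(default_factory=dict)


@dataclass
class SimCohort:
    config: SimConfig
    reference: dict[str, str]
    records_by_sample: dict[str, list[SVRecord]]
    meta: list[SampleMeta]
    truth: SimTruth


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = rng.random(len(arr)) < rate
    if hits.any():
        arr[hits] = rng.choice(BASES, size=int(hits.sum()))
    return arr.tobytes().decode()


def _qual(rng: np.random.Generator, spec: tuple[float, float]) -> float:
    return round(float(max(0.0, rng.normal(*spec))), 4)


def _draw_sites(cfg: SimConfig, rng: np.random.Generator,
                reference: dict[str, str]) -> list[SiteDef]:
    chroms = sorted(reference)
    types = rng.choice(3, size=cfg.n_sites, p=list(cfg.type_mix))
    alu_motif = _random_seq(rng, 300)
    sizes = np.where(
        rng.random(cfg.n_sites) < cfg.alu_fraction,
        np.clip(rng.normal(300, 30, cfg.n_sites), 250, 350),
        np.clip(50 * np.exp(rng.exponential(cfg.size_log_scale, cfg.n_sites)), 50, cfg.size_max),
    ).astype(int)
    per_chrom = math.ceil(cfg.n_sites / len(chroms))
    sites: list[SiteDef] = []
    j = 0
    for chrom in chroms:
        pos = 5000
        for _ in range(per_chrom):
            if j >= cfg.n_sites:
                break
            svtype = (SVType.DEL, SVType.INS, SVType.INV)[types[j]]
            L = int(sizes[j])
            if svtype == SVType.DEL:
                ref = reference[chrom][pos:pos + L + 1]
                alt = ref[0]
            elif svtype == SVType.INS:
                ref = reference[chrom][pos]
                if 250 <= L <= 350:
                    ins = _mutate(rng, (alu_motif * 2)[:L], 0.03)
                else:
                    ins = _random_seq(rng, L)
                alt = ref + ins
            else:
                ref = reference[chrom][pos:pos + L]
                alt = reverse_complement(ref)
            sites.append(SiteDef(j, chrom, pos, svtype, sv_length(ref, alt, svtype), ref, alt))
            pos += L + int(rng.integers(2500, 6000))
            j += 1
        if pos > cfg.chrom_length:
            raise ValueError("chrom_length too small for the requested site count")
    sites.sort(key=lambda s: (s.chrom, s.start))
    for k, s in enumerate(sites):
        s.site_index = k
    return sites


def _solve_intercept(eta_no_b0: np.ndarray, target: float) -> float:
    lo, hi = -20.0, 20.0
    for _ in range(100):
        mid = (lo + hi) / 2
        mean_p = float(np.mean(1 / (1 + np.exp(-(eta_no_b0 + mid)))))
        if mean_p < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Generate per-sample SV callsets, metadata, and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    reference = {f"chr{c + 1}": _random_seq(rng, cfg.chrom_length)
                 for c in range(cfg.n_chroms)}
    sites = _draw_sites(cfg, rng, reference)
    m = len(sites)
    base_afs = np.clip(rng.beta(*cfg.af_beta, size=m), cfg.af_min, 1 - cfg.af_min)
    if cfg.fst > 0:
        a = base_afs * (1 - cfg.fst) / cfg.fst
        b = (1 - base_afs) * (1 - cfg.fst) / cfg.fst
        pop_afs = np.clip(rng.beta(a, b, size=(cfg.n_pops, m)), 1e-4, 1 - 1e-4)
    else:
        pop_afs = np.tile(base_afs, (cfg.n_pops, 1))

    n = cfg.n_pops * cfg.n_per_pop
    pop_of = np.repeat(np.arange(cfg.n_pops), cfg.n_per_pop)
    genotypes = rng.binomial(2, pop_afs[pop_of, :])

    sexes = rng.choice(["F", "M"], size=n)
    centers = [f"C{rng.integers(cfg.n_centers) + 1}" for _ in range(n)]
    studies = [f"ST{(i % cfg.n_studies) + 1}" for i in range(n)]
    read_lengths = np.where(rng.random(n) < cfg.read_length_alt_fraction, 100, 150)

    causal = dict(cfg.causal_effects)
    eta = np.zeros(n)
    for s_idx, orr in causal.items():
        eta += math.log(orr) * genotypes[:, s_idx]
    eta += cfg.sex_log_or * (sexes == "M")
    eta += cfg.center_log_or * (np.array(centers) == "C1")
    b0 = _solve_intercept(eta, cfg.case_fraction)
    case = rng.random(n) < 1 / (1 + np.exp(-(eta + b0)))

    meta: list[SampleMeta] = []
    records_by_sample: dict[str, list[SVRecord]] = {}
    call_labels: dict[str, bool] = {}
    for i in range(n):
        sid = f"S{i + 1:04d}"
        meta.append(SampleMeta(
            sample_id=sid, individual_id=f"I{i + 1:04d}",
            study=studies[i], read_length=int(read_lengths[i]),
            center=centers[i], pcr_free=bool(rng.random() < 0.8),
            sex=str(sexes[i]), status="case" if case[i] else "control",
            ancestry=ANCESTRIES[pop_of[i] % len(ANCESTRIES)],
        ))
        recs = []
        for s in sites:
            dose = genotypes[i, s.site_index]
            if dose == 0:
                continue
            rid = f"{sid}:{s.chrom}:{s.start}"
            recs.append(SVRecord(
                record_id=rid, sample_id=sid, chrom=s.chrom, start=s.start,
                end=s.end, ref_allele=s.ref_allele, alt_allele=s.alt_allele,
                svtype=s.svtype, svlen=s.svlen, qual=_qual(rng, cfg.qual_true),
                genotype=Genotype.het if dose == 1 else Genotype.hom_alt,
            ))
            call_labels[rid] = True
        records_by_sample[sid] = recs

    truth = SimTruth(genotypes=genotypes, sites=sites, base_afs=base_afs,
                     pop_afs=pop_afs, causal=causal,
                     case_status=np.asarray(case), call_labels=call_labels)
    cohort = SimCohort(cfg, reference, records_by_sample, meta, truth)
    if cfg.replicate_individuals > 0:
        simulate_replicates(cohort)
    return cohort


def simulate_replicates(cohort: SimCohort) -> list[SampleMeta]:
    """Add replicate samples (same individual, second sequencing run).

    Each replicated call may be dropped (``replicate_dropout``), has its
    breakpoints jittered by Normal(0, jitter_sd), and its allele bases
    mutated at ``seq_error_rate``; false calls are injected at
    ``false_call_rate`` per true call with qualities drawn from the false
    distribution. Updates the cohort in place and returns the new metadata.
    """
    cfg = cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    base_ids = [m.sample_id for m in cohort.meta[:cfg.replicate_individuals]]
    new_meta = []
    for sid in base_ids:
        orig_meta = next(m for m in cohort.meta if m.sample_id == sid)
        rep_id = f"{sid}r"
        recs: list[SVRecord] = []
        originals = cohort.records_by_sample[sid]
        for r in originals:
            if rng.random() < cfg.replicate_dropout:
                continue
            jitter = int(round(rng.normal(0, cfg.breakpoint_jitter_sd))) if cfg.breakpoint_jitter_sd > 0 else 0
            start = max(0, r.start + jitter)
            ref = _mutate(rng, r.ref_allele, cfg.seq_error_rate)
            alt = _mutate(rng, r.alt_allele, cfg.seq_error_rate)
            if r.svtype in (SVType.DEL, SVType.INS):
                # keep the anchor bases equal so allele roles stay resolved
                ref = r.ref_allele[0] + ref[1:]
                alt = r.alt_allele[0] + alt[1:]
            rid = f"{rep_id}:{r.chrom}:{start}"
            recs.append(SVRecord(
                record_id=rid, sample_id=rep_id, chrom=r.chrom, start=start,
                end=start + len(ref), ref_allele=ref, alt_allele=alt,
                svtype=r.svtype, svlen=sv_length(ref, alt, r.svtype),
                qual=_qual(rng, cfg.qual_true), genotype=r.genotype,
            ))
            cohort.truth.call_labels[rid] = True
        n_false = rng.poisson(cfg.false_call_rate * max(len(originals), 1))
        for k in range(n_false):
            chrom = sorted(cohort.reference)[int(rng.integers(len(cohort.reference)))]
            L = int(np.clip(50 * np.exp(rng.exponential(1.0)), 50, 2000))
            pos = int(rng.integers(1000, len(cohort.reference[chrom]) - L - 1000))
            if rng.random() < 0.5:
                ref = cohort.reference[chrom][pos:pos + L + 1]
                alt = ref[0]
                svtype = SVType.DEL
            else:
                ref = cohort.reference[chrom][pos]
                alt = ref + _random_seq(rng, L)
                svtype = SVType.INS
            rid = f"{rep_id}:FP{k}:{chrom}:{pos}"
            recs.append(SVRecord(
                record_id=rid, sample_id=rep_id, chrom=chrom, start=pos,
                end=pos + len(ref), ref_allele=ref, alt_allele=alt,
                svtype=svtype, svlen=sv_length(ref, alt, svtype),
                qual=_qual(rng, cfg.qual_false), genotype=Genotype.het,
            ))
            cohort.truth.call_labels[rid] = False
        recs.sort(key=lambda r: (r.chrom, r.start, r.record_id))
        cohort.records_by_sample[rep_id] = recs
        new_meta.append(dataclasses.replace(orig_meta, sample_id=rep_id))
    cohort.meta.extend(new_meta)
    return new_meta


def max_feasible_r2(p_sv: float, p_snp: float) -> float:
    """Largest attainable r^2 between loci with the given allele frequencies."""
    d_max = min(p_sv * (1 - p_snp), (1 - p_sv) * p_snp,
                p_sv * p_snp, (1 - p_sv) * (1 - p_snp))
    # positive-D association can reach min(pq', p'q); take the better orientation
    d_pos = min(p_sv * (1 - p_snp), (1 - p_sv) * p_snp)
    d_best = max(d_pos, min(p_sv * p_snp, (1 - p_sv) * (1 - p_snp)))
    denom = p_sv * (1 - p_sv) * p_snp * (1 - p_snp)
    return d_best ** 2 / denom


def simulate_tagged_locus(target_r2: float, n: int, p_sv: float = 0.2,
                          p_snp: float = 0.2, same_haplotype: bool = True,
                          seed: int | np.random.Generator = 0,
                          ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate SV and tag-SNP dosages with a specified population r^2.

    ``same_haplotype=True`` places the SV alternate allele on the risk
    (SNP alternate) background, giving positive D. Raises on infeasible
    targets, naming the attainable bound.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    denom = p_sv * (1 - p_sv) * p_snp * (1 - p_snp)
    d = math.sqrt(target_r2 * denom)
    if not same_haplotype:
        d = -d
    f = np.array([
        p_sv * p_snp + d,             # SV-alt & SNP-alt
        p_sv * (1 - p_snp) - d,
        (1 - p_sv) * p_snp - d,
        (1 - p_sv) * (1 - p_snp) + d,
    ])
    if (f < -1e-12).any():
        bound = max_feasible_r2(p_sv, p_snp)
        raise ValueError(
            f"target r2={target_r2:.3f} infeasible for AFs ({p_sv}, {p_snp}); "
            f"maximum attainable r2 is {bound:.3f}")
    f = np.clip(f, 0, 1)
    f /= f.sum()
    haps = rng.multinomial(1, f, size=2 * n).argmax(axis=1)
    sv_allele = (haps < 2).astype(int)   # haplotypes 0,1 carry the SV alt
    snp_allele = ((haps == 0) | (haps == 2)).astype(int)
    sv_dos = sv_allele.reshape(n, 2).sum(axis=1).astype(float)
    snp_dos = snp_allele.reshape(n, 2).sum(axis=1).astype(float)
    hap_counts = np.bincount(haps, minlength=4) / (2 * n)
    pa, pb = hap_counts[0] + hap_counts[1], hap_counts[0] + hap_counts[2]
    d_real = hap_counts[0] - pa * pb
    realized = d_real ** 2 / (pa * (1 - pa) * pb * (1 - pb)) if 0 < pa < 1 and 0 < pb < 1 else float("nan")
    return sv_dos, snp_dos, {"target_r2": target_r2, "realized_r2": float(realized),
                             "hap_freqs": f.tolist(), "D": float(d)}


def simulate_gene_models(cohort: SimCohort, n_genes: int = 12,
                         seed_offset: int = 11) -> GeneModels:
    """Synthetic representative-transcript gene models over the reference.

    Genes of ~20 kb with 4 exons (first/last carrying UTRs, middle CDS)
    are tiled across each chromosome, deterministically from the cohort
    seed so downstream annotation is reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.config.seed, seed_offset]))
    genes: dict[str, tuple[str, int, int]] = {}
    features: list[GeneFeature] = []
    chroms = sorted(cohort.reference)
    per_chrom = math.ceil(n_genes / len(chroms))
    g = 0
    for chrom in chroms:
        clen = len(cohort.reference[chrom])
        for k in range(per_chrom):
            if g >= n_genes:
                break
            start = int((k + 0.5) * clen / (per_chrom + 1)) + int(rng.integers(0, 2000))
            end = min(start + 20_000, clen)
            gid = f"GENE{g + 1}"
            exon_starts = np.linspace(start, end - 1500, 4).astype(int)
            # gene span runs exactly from first exon start to last exon end,
            # so intron derivation from exon gaps is lossless
            genes[gid] = (chrom, start, int(exon_starts[-1]) + 1200)
            for e_i, es in enumerate(exon_starts):
                ee = int(es) + 1200
                features.append(GeneFeature(chrom, int(es), ee, gid, "exon"))
                if e_i == 0:
                    features.append(GeneFeature(chrom, int(es), int(es) + 300, gid, "utr5"))
                    features.append(GeneFeature(chrom, int(es) + 300, ee, gid, "cds"))
                elif e_i == len(exon_starts) - 1:
                    features.append(GeneFeature(chrom, int(es), ee - 300, gid, "cds"))
                    features.append(GeneFeature(chrom, ee - 300, ee, gid, "utr3"))
                else:
                    features.append(GeneFeature(chrom, int(es), ee, gid, "cds"))
            for es, ee in zip(exon_starts[:-1], exon_starts[1:]):
                features.append(GeneFeature(chrom, int(es) + 1200, int(ee), gid, "intron"))
            g += 1
    return GeneModels(genes=genes, features=features)


def write_gene_models_gff3(models: GeneModels, path: str | Path) -> Path:
    path = Path(path)
    rev = {"cds": "CDS", "utr5": "five_prime_UTR", "utr3": "three_prime_UTR",
           "exon": "exon", "intron": "intron"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, (chrom, s, e) in sorted(models.genes.items()):
            fh.write(f"{chrom}\tsvcohort\tgene\t{s + 1}\t{e}\t.\t+\t.\tID={gid}\n")
        for f in models.features:
            if f.feature == "intron":
                continue  # introns are re-derived from exon gaps on load
            fh.write(f"{f.chrom}\tsvcohort\t{rev[f.feature]}\t{f.start + 1}\t{f.end}"
                     f"\t.\t+\t.\tParent={f.gene_id};gene_id={f.gene_id}\n")
    return path


def simulate_catalog(cohort: SimCohort, known_fraction: float = 0.6,
                     af_noise_sd: float = 0.0, source: str = "synthcat",
                     seed_offset: int = 13) -> list[CatalogEntry]:
    """A known-SV catalog covering a random subset of the true sites.

    Catalog AFs equal the true base AFs plus optional Gaussian noise, so
    AF-concordance behavior is fully controlled.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.config.seed, seed_offset]))
    entries = []
    for s in cohort.truth.sites:
        if rng.random() > known_fraction:
            continue
        af = float(np.clip(cohort.truth.base_afs[s.site_index]
                           + (rng.normal(0, af_noise_sd) if af_noise_sd > 0 else 0.0),
                           0.0, 1.0))
        end = s.end if s.svtype != SVType.INS else s.start + 1
        entries.append(CatalogEntry(source, s.chrom, s.start, max(end, s.start + 1),
                                    s.svtype, af, s.svlen))
    return entries


def simulate_pathogenicity(cohort: SimCohort, models: GeneModels,
                           pathogenic_fraction: float = 0.3,
                           seed_offset: int = 17) -> dict[tuple[str, str], float]:
    """Per-(site, gene) pathogenicity scores in [0, 1] for cohort sites.

    A configurable fraction of (site, gene) pairs receives a score >= 0.5.
    Keys use the truth site id ``{chrom}:{start}``-style record ids of the
    collapsed representative; here keyed by site position id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cohort.config.seed, seed_offset]))
    scores: dict[tuple[str, str], float] = {}
    for s in cohort.truth.sites:
        qe = s.start + 1 if s.svtype == SVType.INS else s.end
        genes = models.overlapping_genes(s.chrom, s.start - 1_000_000, qe + 1_000_000)
        for g in sorted(genes):
            if rng.random() < pathogenic_fraction:
                score = float(rng.uniform(0.5, 1.0))
            else:
                score = float(rng.uniform(0.0, 0.5))
            scores[(f"{s.chrom}:{s.start}", g)] = score
    return scores


def write_fixture_bundle(cohort: SimCohort, outdir: str | Path,
                         force: bool = False) -> Path:
    """Serialize a cohort as a self-describing fixture bundle.

    Emits per-sample VCFs, a metadata TSV, gene models (GFF3), a known-SV
    catalog BED, a pathogenicity TSV, and a truth JSON embedding the
    config. Lossless: re-ingesting the VCFs reproduces the genotypes.
    """
    from svcohort.sv_model import write_sv_vcf  # local import avoids cycle at module load

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is nonempty; pass force=True")
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    for sid, recs in sorted(cohort.records_by_sample.items()):
        write_sv_vcf(sorted(recs, key=lambda r: (r.chrom, r.start, r.record_id)),
                     outdir / "vcf" / f"{sid}.vcf", sample_id=sid)
    with open(outdir / "meta.tsv", "w") as fh:
        fh.write("sample_id\tindividual_id\tstudy\tread_length\tcenter\tpcr_free"
                 "\tsex\tstatus\tancestry\n")
        for m in cohort.meta:
            fh.write(f"{m.sample_id}\t{m.individual_id}\t{m.study}\t{m.read_length}"
                     f"\t{m.center}\t{int(m.pcr_free)}\t{m.sex}\t{m.status}\t{m.ancestry}\n")
    models = simulate_gene_models(cohort)
    write_gene_models_gff3(models, outdir / "genes.gff3")
    catalog = simulate_catalog(cohort)
    with open(outdir / "catalog.bed", "w") as fh:
        for e in catalog:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.svtype.value}\t{e.af}\t{e.svlen}\n")
    scores = simulate_pathogenicity(cohort, models)
    with open(outdir / "pathogenicity.tsv", "w") as fh:
        fh.write("site_id\tgene_id\tscore\n")
        for (sid, gid), sc in sorted(scores.items()):
            fh.write(f"{sid}\t{gid}\t{sc:.4f}\n")
    truth = {
        "config": dataclasses.asdict(cohort.config),
        "sites": [{"chrom": s.chrom, "start": s.start, "svtype": s.svtype.value,
                   "svlen": s.svlen} for s in cohort.truth.sites],
        "base_afs": cohort.truth.base_afs.tolist(),
        "causal": {str(k): v for k, v in cohort.truth.causal.items()},
        "genotypes": cohort.truth.genotypes.tolist(),
        "case_status": cohort.truth.case_status.astype(int).tolist(),
        "call_labels": cohort.truth.call_labels,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh)
    return outdir


def read_meta_tsv(path: str | Path) -> list[SampleMeta]:
    meta = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            meta.append(SampleMeta(
                sample_id=d["sample_id"], individual_id=d["individual_id"],
                study=d["study"], read_length=int(d["read_length"]),
                center=d["center"], pcr_free=bool(int(d["pcr_free"])),
                sex=d["sex"], status=d["status"], ancestry=d["ancestry"]))
    return meta
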