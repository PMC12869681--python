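"""Catalog intersection, AF concordance, and gene-model annotation."""

import numpy as np
import pytest

from svcohort.annotate import (CatalogEntry, GeneAnnotation, GeneFeature,
                               GeneModels, af_concordance, annotate_genes,
                               candidate_gene_report, intersect_catalog,
                               read_gene_models_gff3, reciprocal_overlap)
from svcohort.cohort_qc import CohortCallset
from svcohort.sv_model import SampleMeta, SVType
from svcohort.synthetic_data import simulate_gene_models, write_gene_models_gff3

from conftest import make_record


def _callset(sites, n_samples=20, ac=None):
    dosage = np.zeros((n_samples, len(sites)))
    for j in range(len(sites)):
        k = (ac[j] if ac else 4)
        dosage[:k, j] = 1
    samples = [SampleMeta(f"S{i}", f"S{i}") for i in range(n_samples)]
    return CohortCallset(sites=sites, samples=samples, dosage=dosage)


class TestCatalogIntersection:
    def test_identical_entry_is_known(self):
        site = make_record("d", start=1000, svtype=SVType.DEL, svlen=200)
        cs = _callset([site])
        cat = [CatalogEntry("db", "chr1", site.start, site.end, SVType.DEL, af=0.1)]
        df = intersect_catalog(cs, cat)
        assert bool(df["known"][0])
        assert df["match_score"][0] == pytest.approx(1.0)

    def test_insufficient_reciprocal_overlap_is_novel(self):
        site = make_record("d", start=1000, svtype=SVType.DEL, svlen=99)  # span 100
        cs = _callset([site])
        # 40-bp overlap of two 100-bp intervals -> reciprocal overlap 0.4
        cat = [CatalogEntry("db", "chr1", site.end - 40, site.end - 40 + 100, SVType.DEL)]
        assert reciprocal_overlap(site.start, site.end, cat[0].start, cat[0].end) == pytest.approx(0.4)
        df = intersect_catalog(cs, cat, del_inv_recip_overlap=0.5)
        assert not bool(df["known"][0])

    def test_distant_insertion_is_novel(self):
        site = make_record("i", start=5000, svtype=SVType.INS, svlen=100)
        cs = _callset([site])
        cat = [CatalogEntry("db", "chr1", 6500, 6501, SVType.INS, svlen=100)]
        df = intersect_catalog(cs, cat, ins_max_dist=1000)
        assert not bool(df["known"][0])

    def test_type_mismatch_is_novel(self):
        site = make_record("d", start=1000, svtype=SVType.DEL, svlen=200)
        cs = _callset([site])
        cat = [CatalogEntry("db", "chr1", site.start, site.end, SVType.INV)]
        assert not bool(intersect_catalog(cs, cat)["known"][0])

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        sites, cat = [], []
        pos = 1000
        for i in range(25):
            svtype = [SVType.DEL, SVType.INS, SVType.INV][rng.integers(3)]
            svlen = int(rng.integers(50, 500))
            sites.append(make_record(f"s{i}", start=pos, svtype=svtype, svlen=svlen, rng=rng))
            pos += svlen + int(rng.integers(2000, 5000))
        for _ in range(40):
            svtype = [SVType.DEL, SVType.INS, SVType.INV][rng.integers(3)]
            start = int(rng.integers(500, pos))
            length = int(rng.integers(50, 500))
            cat.append(CatalogEntry("db", "chr1", start, start + length, svtype,
                                    svlen=length))
        cs = _callset(sites)
        df = intersect_catalog(cs, cat)
        for j, site in enumerate(sites):  # O(n*m) scan
            known = False
            for e in cat:
                if e.svtype != site.svtype:
                    continue
                if site.svtype == SVType.INS:
                    from svcohort.sv_compare import size_similarity
                    if (abs(site.start - e.start) <= 1000
                            and size_similarity(site.svlen, e.length) >= 0.5):
                        known = True
                elif reciprocal_overlap(site.start, site.end, e.start, e.end) >= 0.5:
                    known = True
            assert bool(df["known"][j]) == known, site.record_id


class TestAfConcordance:
    def _df(self, cohort_af, catalog_af):
        import pandas as pd
        return pd.DataFrame({"known": True, "cohort_af": cohort_af,
                             "matched_af": catalog_af})

    def test_duplicated_af_gives_r2_one(self):
        af = np.linspace(0.02, 0.5, 20)
        r2, p = af_concordance(self._df(af, af.copy()))
        assert r2 == pytest.approx(1.0)
        assert p < 0.01

    def test_noisy_af_matches_attenuation_formula(self):
        rng = np.random.default_rng(55)
        af = rng.uniform(0.05, 0.5, 500)
        noisy = af + rng.normal(0, 0.05, 500)
        r2, _ = af_concordance(self._df(af, noisy))
        expected = np.var(af) / (np.var(af) + 0.0025)
        assert r2 == pytest.approx(expected, abs=0.05)

    def test_independent_afs_give_near_zero_r2(self):
        rng = np.random.default_rng(56)
        r2, _ = af_concordance(self._df(rng.uniform(0.05, 0.5, 500),
                                        rng.uniform(0.05, 0.5, 500)))
        assert r2 < 0.02

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            af_concordance(self._df([0.1, 0.2], [0.1, 0.2]))


def toy_models():
    """One gene on chr1: span [10_000, 30_000), exon1 with utr5+cds,
    intron, exon2 with cds+utr3."""
    genes = {"G1": ("chr1", 10_000, 30_000)}
    feats = [
        GeneFeature("chr1", 10_000, 12_000, "G1", "exon"),
        GeneFeature("chr1", 10_000, 10_500, "G1", "utr5"),
        GeneFeature("chr1", 10_500, 12_000, "G1", "cds"),
        GeneFeature("chr1", 12_000, 28_000, "G1", "intron"),
        GeneFeature("chr1", 28_000, 30_000, "G1", "exon"),
        GeneFeature("chr1", 28_000, 29_500, "G1", "cds"),
        GeneFeature("chr1", 29_500, 30_000, "G1", "utr3"),
    ]
    return GeneModels(genes=genes, features=feats)


class TestGeneAnnotation:
    def test_del_spanning_exon_intron_junction(self):
        site = make_record("d", start=11_900, svtype=SVType.DEL, svlen=299)
        cs = _callset([site])
        (a,) = annotate_genes(cs, toy_models())
        assert a.klass == "gene_overlap"
        assert a.features == {"exon", "cds", "intron"}
        assert a.gene_ids == ("G1",)

    def test_proximal_within_5kb(self):
        # ends 4999 bp upstream of the gene start
        site = make_record("d", start=4901, svtype=SVType.DEL, svlen=99)  # end 5001
        cs = _callset([site])
        (a,) = annotate_genes(cs, toy_models())
        assert a.klass == "proximal_5kb"

    def test_beyond_5kb_is_intergenic(self):
        site = make_record("d", start=1000, svtype=SVType.DEL, svlen=99)
        cs = _callset([site])
        (a,) = annotate_genes(cs, toy_models())
        assert a.klass == "intergenic"

    def test_insertion_annotated_by_anchor_base_only(self):
        # anchor in the intron; a span of this length would also hit exon2
        site = make_record("i", start=20_000, svtype=SVType.INS, svlen=15_000)
        cs = _callset([site])
        (a,) = annotate_genes(cs, toy_models())
        assert a.klass == "gene_overlap"
        assert a.features == {"intron"}

    def test_classes_exclusive_and_exhaustive(self, small_cohort):
        from svcohort.cohort_qc import build_cohort
        meta = [m for m in small_cohort.meta if not m.sample_id.endswith("r")]
        recs = {m.sample_id: small_cohort.records_by_sample[m.sample_id] for m in meta}
        cs = build_cohort(recs, meta)
        models = simulate_gene_models(small_cohort)
        anns = annotate_genes(cs, models)
        assert len(anns) == len(cs.sites)
        assert all(a.klass in ("gene_overlap", "proximal_5kb", "intergenic") for a in anns)

    def test_gff3_round_trip(self, small_cohort, tmp_path):
        models = simulate_gene_models(small_cohort)
        write_gene_models_gff3(models, tmp_path / "g.gff3")
        loaded = read_gene_models_gff3(tmp_path / "g.gff3")
        assert loaded.genes == models.genes
        orig_feats = {(f.chrom, f.start, f.end, f.gene_id, f.feature)
                      for f in models.features}
        load_feats = {(f.chrom, f.start, f.end, f.gene_id, f.feature)
                      for f in loaded.features}
        assert load_feats == orig_feats


class TestCandidateGeneReport:
    def _setup(self, af):
        site = make_record("d", start=10_400, svtype=SVType.DEL, svlen=199)  # hits utr5+cds
        n = 100
        cs = _callset([site], n_samples=n, ac=[max(1, int(af * 2 * n))])
        anns = annotate_genes(cs, toy_models())
        return cs, anns

    def test_common_sv_in_listed_gene_included(self):
        cs, anns = self._setup(0.05)
        df = candidate_gene_report(cs, anns, ["G1"])
        assert list(df["gene"]) == ["G1"]

    def test_rare_sv_excluded(self):
        cs, anns = self._setup(0.005)
        assert candidate_gene_report(cs, anns, ["G1"]).empty

    def test_intronic_only_excluded(self):
        site = make_record("d", start=15_000, svtype=SVType.DEL, svlen=200)
        cs = _callset([site], n_samples=100, ac=[20])
        anns = annotate_genes(cs, toy_models())
        assert anns[0].features == {"intron"}
        assert candidate_gene_report(cs, anns, ["G1"]).empty
        kept = candidate_gene_report(cs, anns, ["G1"], exclude_intronic_only=False)
        assert len(kept) == 1
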