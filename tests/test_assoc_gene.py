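"""Burden, SKAT, hybrid set tests, set construction, FDR, and gene meta-analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from svcohort.assoc_gene import (NullModel, PathogenicityCall, SetMember,
                                 VariantSet, bh_fdr, build_sets, burden_test,
                                 classify_sv, conditional_set_test, liu_sf,
                                 meta_gene, skat_test, smmat_e, variant_weight)
from svcohort.assoc_single import score_test
from svcohort.sv_model import SVType

from conftest import make_record
from test_annotate import toy_models


def _null_setup(rng, n=1200, n_var=5, maf_range=(0.01, 0.05)):
    y = (rng.random(n) < 0.47).astype(float)
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    mafs = rng.uniform(*maf_range, n_var)
    G = rng.binomial(2, mafs, (n, n_var)).astype(float)
    members = [SetMember(f"v{j}", G[:, j], float(mafs[j]),
                         weight=variant_weight(float(mafs[j])))
               for j in range(n_var)]
    return y, X, VariantSet("G1", "pLoF", members)


class TestSingleVariantReduction:
    def test_burden_skat_and_score_test_agree(self):
        rng = np.random.default_rng(0)
        n = 800
        y = (rng.random(n) < 0.5).astype(float)
        X = np.ones((n, 1))
        g = rng.binomial(2, 0.03, n).astype(float)
        vset = VariantSet("G", "pLoF", [SetMember("v", g, 0.03, weight=1.0)])
        null = NullModel(y, X)
        _, p_burden = burden_test(vset, null)
        _, p_skat = skat_test(vset, null)
        z, p_score = score_test(y, g, X)
        assert p_burden == pytest.approx(p_score, abs=1e-8)
        assert p_skat == pytest.approx(p_score, abs=1e-8)

    def test_hybrid_on_single_variant_is_valid_probability(self):
        rng = np.random.default_rng(1)
        y, X, _ = _null_setup(rng)
        g = rng.binomial(2, 0.02, len(y)).astype(float)
        vset = VariantSet("G", "pLoF", [SetMember("v", g, 0.02, weight=1.0)])
        p = smmat_e(vset, NullModel(y, X))
        assert 0 < p <= 1


class TestLiuMomentMatching:
    def test_single_eigenvalue_reduces_to_chi2(self):
        for lam, q in [(1.0, 3.84), (2.5, 10.0), (0.3, 0.5)]:
            assert liu_sf(q, np.array([lam])) == pytest.approx(
                stats.chi2.sf(q / lam, 1), abs=1e-10)

    @pytest.mark.parametrize("lambdas", [
        [1.0, 1.0, 1.0], [5.0, 1.0, 0.2], [3.0, 2.0, 1.0, 0.5, 0.1]])
    def test_matches_monte_carlo_mixture(self, lambdas):
        lam = np.array(lambdas)
        rng = np.random.default_rng(99)
        draws = rng.chisquare(1, (100_000, len(lam))) @ lam
        q = float(np.quantile(draws, 0.95))
        p_mc = float((draws > q).mean())
        p_liu = liu_sf(q, lam)
        assert p_liu == pytest.approx(p_mc, rel=0.10)


class TestPlantedEffects:
    def test_burden_detects_strong_carrier_case_enrichment(self):
        rng = np.random.default_rng(2)
        detected = 0
        for _ in range(20):
            n = 1000
            y = np.zeros(n)
            G = rng.binomial(2, rng.uniform(0.005, 0.01, 4), (n, 4)).astype(float)
            carriers = G.sum(axis=1) > 0
            y[carriers] = 1.0                      # all carriers are cases
            y[~carriers] = rng.random((~carriers).sum()) < 0.4
            members = [SetMember(f"v{j}", G[:, j], 0.008, weight=1.0) for j in range(4)]
            vset = VariantSet("G", "pLoF", members)
            _, p = burden_test(vset, NullModel(y, np.ones((n, 1))))
            if p < 1e-4:
                detected += 1
        assert detected >= 19

    def test_hybrid_beats_skat_for_unidirectional_effects(self):
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(30):
            n = 1500
            mafs = rng.uniform(0.005, 0.02, 5)
            G = rng.binomial(2, mafs, (n, 5)).astype(float)
            eta = -0.3 + G @ np.full(5, 0.8)       # shared-direction effects
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            members = [SetMember(f"v{j}", G[:, j], float(mafs[j]), weight=1.0)
                       for j in range(5)]
            vset = VariantSet("G", "pLoF", members)
            null = NullModel(y, np.ones((n, 1)))
            _, p_skat = skat_test(vset, null)
            if smmat_e(vset, null) <= p_skat:
                wins += 1
        assert wins >= 24  # >= 80% of replicates

    def test_zero_dosage_member_does_not_change_statistics(self):
        rng = np.random.default_rng(4)
        y, X, vset = _null_setup(rng)
        null = NullModel(y, X)
        p0 = smmat_e(vset, null)
        augmented = VariantSet(vset.gene_id, vset.category,
                               vset.members + [SetMember("null", np.zeros(len(y)),
                                                         0.001, weight=2.0)])
        assert smmat_e(augmented, null) == pytest.approx(p0, abs=1e-12)
        assert burden_test(augmented, null)[1] == pytest.approx(
            burden_test(vset, null)[1], abs=1e-12)


class TestClassifySv:
    def test_one_bp_exon_overlap_is_coding(self):
        # exon1 of the toy gene ends at 12_000; deletion [11_999, 12_100)
        sv = make_record("d", start=11_949, svtype=SVType.DEL, svlen=100)
        assert sv.end > 12_000 or sv.start < 12_000
        calls = classify_sv(sv, toy_models(), {("d", "G1"): 0.7})
        assert calls == [PathogenicityCall("d", "G1", 0.7, True)]
        assert calls[0].is_pathogenic

    def test_score_boundary_at_half(self):
        sv = make_record("d", start=10_500, svtype=SVType.DEL, svlen=100)
        (call,) = classify_sv(sv, toy_models(), {("d", "G1"): 0.5})
        assert call.is_pathogenic
        (call,) = classify_sv(sv, toy_models(), {("d", "G1"): 0.4999})
        assert not call.is_pathogenic

    def test_noncoding_sv_beyond_1mb_gets_no_call(self):
        sv = make_record("d", start=1_200_000 + 30_000, svtype=SVType.DEL, svlen=100)
        assert classify_sv(sv, toy_models(), {}) == []

    def test_intronic_sv_evaluated_as_noncoding(self):
        sv = make_record("d", start=15_000, svtype=SVType.DEL, svlen=100)
        (call,) = classify_sv(sv, toy_models(), {("d", "G1"): 0.9})
        assert not call.is_coding and call.is_pathogenic


class TestBuildSets:
    def _members(self, rng, n=400):
        def mk(maf):
            return SetMember("x", rng.binomial(2, maf, n).astype(float), maf)
        return mk

    def test_low_cmac_set_excluded(self):
        g = np.zeros(400)
        g[:9] = 1.0  # cMAC 9
        call = PathogenicityCall("sv1", "G1", 0.8, True)
        sets = build_sets([], [(call, SetMember("sv1", g, 0.005))], mode="sv_only")
        assert sets == []
        g2 = np.zeros(400)
        g2[:10] = 1.0
        sets = build_sets([], [(PathogenicityCall("sv2", "G1", 0.8, True),
                                SetMember("sv2", g2, 0.005))], mode="sv_only")
        assert len(sets) == 1 and sets[0].cmac == 10

    def test_common_variant_excluded_from_members(self):
        rng = np.random.default_rng(5)
        mk = self._members(rng)
        snvs = [("G1", "pLoF", mk(0.012)), ("G1", "pLoF", mk(0.005))]
        sets = build_sets(snvs, [], mode="combined", cmac_min=1)
        assert len(sets[0].members) == 1

    def test_benign_sv_excluded(self):
        g = np.ones(400)
        call = PathogenicityCall("sv1", "G1", 0.3, True)
        assert build_sets([], [(call, SetMember("sv1", g, 0.005))], mode="sv_only") == []

    def test_union_semantics_in_combined_mode(self):
        rng = np.random.default_rng(6)
        mk = self._members(rng)
        snvs = [("G1", "pLoF", mk(0.008)) for _ in range(9)]
        svs = []
        for i in range(2):
            g = np.zeros(400)
            g[:20] = 1.0
            svs.append((PathogenicityCall(f"sv{i}", "G1", 0.9, True),
                        SetMember(f"sv{i}", g, 0.008)))
        sets = build_sets(snvs, svs, mode="combined", cmac_min=1)
        (s,) = [s for s in sets if s.category == "pLoF"]
        assert len(s.members) == 11
        assert sum(m.is_sv for m in s.members) == 2

    def test_noncoding_sv_not_mixed_into_coding_category(self):
        rng = np.random.default_rng(7)
        mk = self._members(rng)
        snvs = [("G1", "pLoF", mk(0.008))]
        g = np.zeros(400)
        g[:20] = 1.0
        svs = [(PathogenicityCall("sv1", "G1", 0.9, False), SetMember("sv1", g, 0.008))]
        sets = build_sets(snvs, svs, mode="combined", cmac_min=1)
        (s,) = sets
        assert not any(m.is_sv for m in s.members)


class TestConditionalSetTest:
    def test_independent_sv_signal_survives_snv_conditioning(self):
        rng = np.random.default_rng(8)
        survived = 0
        for _ in range(10):
            n = 2000
            g_sv = rng.binomial(1, 0.01, n).astype(float)
            g_snv = rng.binomial(2, 0.01, (n, 3)).astype(float)
            eta = -0.2 + 2.0 * g_sv
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            sv_set = VariantSet("G", "sv_coding", [SetMember("sv", g_sv, 0.01, weight=1.0)])
            snv_set = VariantSet("G", "pLoF",
                                 [SetMember(f"s{j}", g_snv[:, j], 0.01, weight=1.0)
                                  for j in range(3)])
            p = conditional_set_test(sv_set, snv_set, y, np.ones((n, 1)))
            if p < 0.05:
                survived += 1
        assert survived >= 9

    def test_empty_set_rejected(self):
        vs = VariantSet("G", "c", [SetMember("v", np.ones(10), 0.005)])
        empty = VariantSet("G", "c", [])
        with pytest.raises(ValueError):
            conditional_set_test(empty, vs, np.zeros(10), np.ones((10, 1)))


class TestFdrAndMeta:
    def test_bh_step_up_hand_computed(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_meta_two_equal_groups_closed_form(self):
        p = 0.01
        z = stats.norm.isf(p)
        expected = stats.norm.sf(2 * math.sqrt(500) * z / math.sqrt(1000))
        assert meta_gene([p, p], [500, 500]) == pytest.approx(expected, rel=1e-10)

    def test_weak_group_dilutes_strong_group(self):
        strong = meta_gene([1e-6, 1e-6], [1000, 1000])
        diluted = meta_gene([1e-6, 0.9], [1000, 1000])
        assert diluted > strong

    def test_consistency_with_single_variant_stouffer(self):
        from svcohort.assoc_single import stouffer_meta
        pvals, ns = [0.02, 0.3], [800, 1200]
        zs = [float(stats.norm.isf(p)) for p in pvals]
        z_meta, _ = stouffer_meta(zs, ns)
        assert meta_gene(pvals, ns) == pytest.approx(float(stats.norm.sf(z_meta)))
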