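"""Exome filter cascade: site/genotype/no-call filters, classes, segregation."""

import math

import pytest

from consangmap import (
    FilterThresholds,
    GenotypeCall,
    SegregationRule,
    SynthConfig,
    VariantRecord,
    allele_balance_p,
    apply_genotype_filters,
    family_fixtures,
    frequency_class,
    generate_variant_table,
    genotype_filter,
    is_damaging,
    known_variant_screen,
    no_call_filter,
    parent_genotype_constraint,
    proband_candidates,
    read_vcf,
    segregation_filter,
    site_filter,
    write_vcf,
)
from consangmap.synth import CandidateSpec, DecoySpec
from consangmap.variants import HET, HOM_ALT, HOM_REF, NO_CALL, attach_annotations
from conftest import PRIORITISED_ROWS, prioritised_variant_records

T = FilterThresholds()
POPS = ("primary", "secondary")


def mkvar(**kw):
    base = dict(chrom="1", pos=100, ref="A", alt="G")
    base.update(kw)
    return VariantRecord(**base)


class TestSiteFilter:
    def test_snp_above_tranche_dropped(self):
        assert site_filter([mkvar(tranche_sensitivity=99.6)]) == []

    def test_indel_at_boundary_retained(self):
        v = mkvar(ref="A", alt="AT", tranche_sensitivity=99.0)
        assert site_filter([v]) == [v]

    def test_indel_above_its_tranche_dropped(self):
        assert site_filter([mkvar(ref="A", alt="AT", tranche_sensitivity=99.2)]) == []

    def test_pass_flag_without_tranche_retained(self):
        v = mkvar(filter_pass=True)
        assert site_filter([v]) == [v]


class TestAlleleBalance:
    def test_balanced_depths_p_one(self):
        assert allele_balance_p(10, 10) == 1.0

    def test_thirty_zero_fails_threshold(self):
        # chi2 = 30 on 1 df; closed form erfc(sqrt(15))
        p = allele_balance_p(30, 0)
        assert p == pytest.approx(math.erfc(math.sqrt(15.0)), rel=1e-9)
        assert p < 0.001

    def test_eighteen_seven_passes(self):
        p = allele_balance_p(18, 7)
        assert p == pytest.approx(math.erfc(math.sqrt(4.84 / 2)), rel=1e-9)
        assert p > 0.001

    def test_zero_depth_is_error(self):
        with pytest.raises(ValueError):
            allele_balance_p(0, 0)


class TestGenotypeFilter:
    def test_low_gq_het_nocalled(self):
        call = GenotypeCall(gt=HET, gq=29, ref_depth=20, alt_depth=20)
        assert genotype_filter(call, "snp").gt == NO_CALL

    def test_hom_alt_low_alt_depth_nocalled(self):
        call = GenotypeCall(gt=HOM_ALT, gq=99, ref_depth=0, alt_depth=2)
        assert genotype_filter(call, "snp").gt == NO_CALL

    def test_imbalanced_het_nocalled(self):
        call = GenotypeCall(gt=HET, gq=99, ref_depth=60, alt_depth=4)
        assert genotype_filter(call, "snp").gt == NO_CALL

    def test_hom_ref_untouched(self):
        call = GenotypeCall(gt=HOM_REF, gq=99, ref_depth=40, alt_depth=0)
        assert genotype_filter(call, "snp") == call


class TestNoCallFilter:
    def make(self, n_no_call, n=10):
        genotypes = {
            f"S{k}": GenotypeCall(gt=NO_CALL if k < n_no_call else HOM_REF)
            for k in range(n)
        }
        return mkvar(genotypes=genotypes)

    def test_thirty_percent_dropped(self):
        assert no_call_filter([self.make(3)]) == []

    def test_twenty_percent_retained(self):
        assert len(no_call_filter([self.make(2)])) == 1

    def test_fully_called_retained(self):
        assert len(no_call_filter([self.make(0)])) == 1


class TestFrequencyClass:
    def test_rare_in_both_populations(self):
        v = mkvar(maf={"primary": 0.0054, "secondary": 0.0044})
        assert frequency_class(v, POPS) == "rare"

    def test_absent_in_both_is_very_rare(self):
        v = mkvar(maf={"primary": None, "secondary": None})
        assert frequency_class(v, POPS) == "very_rare"

    def test_rarer_population_does_not_rescue(self):
        v = mkvar(maf={"primary": 0.0072, "secondary": 0.0146})
        assert frequency_class(v, POPS) == "uncommon"

    def test_any_population_at_five_percent_is_common(self):
        v = mkvar(maf={"primary": 0.0001, "secondary": 0.05})
        assert frequency_class(v, POPS) == "common"

    def test_boundaries_join_the_rarer_class(self):
        assert frequency_class(mkvar(maf={"primary": 0.01}), ("primary",)) == "rare"
        assert frequency_class(mkvar(maf={"primary": 0.001}), ("primary",)) == "very_rare"

    @pytest.mark.parametrize("low,high", [(0.0, 0.0005), (0.0005, 0.005),
                                          (0.005, 0.03), (0.03, 0.2)])
    def test_monotone_in_maf(self, low, high):
        """Increasing any population MAF never makes the class rarer."""
        order = ["very_rare", "rare", "uncommon", "common"]
        lo = frequency_class(mkvar(maf={"primary": low, "secondary": 0.004}), POPS)
        hi = frequency_class(mkvar(maf={"primary": high, "secondary": 0.004}), POPS)
        assert order.index(hi) >= order.index(lo)


class TestDamaging:
    def test_stop_gained_without_scores(self):
        assert is_damaging(mkvar(consequence="stop_gained"))

    def test_missense_rescued_by_cadd(self):
        v = mkvar(consequence="missense", sift="tolerated", polyphen="benign",
                  cadd_phred=23.9)
        assert is_damaging(v)

    def test_missense_rescued_by_low_confidence_sift(self):
        v = mkvar(consequence="missense", sift="deleterious_lc", polyphen="benign",
                  cadd_phred=3.083)
        assert is_damaging(v)

    def test_synonymous_gated_regardless_of_cadd(self):
        assert not is_damaging(mkvar(consequence="synonymous", cadd_phred=25.0))

    def test_cadd_threshold_is_strict(self):
        v = mkvar(consequence="missense", sift="tolerated", polyphen="benign",
                  cadd_phred=20.0)
        assert not is_damaging(v)

    def test_all_prioritised_rows_classify_as_damaging_and_subcommon(self):
        """Every published prioritised variant is damaging and uncommon-or-rarer
        under the dual-population rule."""
        for v, row in zip(prioritised_variant_records(), PRIORITISED_ROWS):
            assert is_damaging(v), row[0]
            assert frequency_class(v, POPS) in ("uncommon", "rare", "very_rare"), row[0]


def candidate_set(proband="P", sibs=("P", "S"), controls=("C1", "C2", "C3")):
    """One clean candidate plus genotype variations used by selection tests."""
    genotypes = {s: GenotypeCall(gt=HOM_ALT, gq=99, ref_depth=0, alt_depth=30)
                 for s in sibs}
    genotypes.update({c: GenotypeCall(gt=HOM_REF, gq=99, ref_depth=30, alt_depth=0)
                      for c in controls})
    return mkvar(consequence="missense", sift="deleterious",
                 maf={"primary": 0.004, "secondary": 0.002}, genotypes=genotypes)


class TestCandidateSelection:
    def test_hom_damaging_rare_included(self):
        v = candidate_set()
        assert proband_candidates([v], "P", POPS) == [v]

    def test_het_proband_excluded(self):
        v = candidate_set()
        v.genotypes["P"] = GenotypeCall(gt=HET, gq=99, ref_depth=15, alt_depth=15)
        assert proband_candidates([v], "P", POPS) == []

    def test_common_variant_excluded(self):
        v = candidate_set()
        v.maf = {"primary": 0.06, "secondary": 0.002}
        assert proband_candidates([v], "P", POPS) == []

    def test_segregation_all_sibs_with_control_annotation(self):
        v = candidate_set()
        out = segregation_filter([v], SegregationRule("all"), ("P", "S"),
                                 ("C1", "C2", "C3"))
        assert out == [(v, "0/3")]

    def test_one_of_two_sibs_under_all_rule_dropped(self):
        v = candidate_set(sibs=("P",))
        v.genotypes["S"] = GenotypeCall(gt=HET, gq=99, ref_depth=15, alt_depth=15)
        assert segregation_filter([v], SegregationRule("all"), ("P", "S"), ()) == []

    def test_two_of_three_sibs_under_min_count_rule_kept(self):
        v = candidate_set(sibs=("P", "S"))
        v.genotypes["S2"] = GenotypeCall(gt=HET, gq=99, ref_depth=15, alt_depth=15)
        out = segregation_filter([v], SegregationRule(2), ("P", "S", "S2"), ())
        assert len(out) == 1


class TestParentInference:
    def test_hom_ref_descendant_excludes_parent_homozygosity(self):
        calls = [GenotypeCall(gt=HOM_REF), GenotypeCall(gt=HET)]
        assert parent_genotype_constraint(calls) == "hom_alt_excluded"

    def test_all_het_descendants_leave_it_possible(self):
        calls = [GenotypeCall(gt=HET), GenotypeCall(gt=HET)]
        assert parent_genotype_constraint(calls) == "hom_alt_possible"

    def test_hom_alt_descendant_possible(self):
        assert parent_genotype_constraint([GenotypeCall(gt=HOM_ALT)]) == "hom_alt_possible"


class TestKnownVariantScreen:
    def test_absent_panel_variant_reported_absent(self):
        table = known_variant_screen([], [("2", 234183368, "A", "G", "T300A")], ["S1"])
        assert set(table["genotype"]) == {"absent"}

    def test_planted_risk_allele_homozygotes_counted(self):
        carriers = [f"case{k}" for k in range(3)] + [f"ctrl{k}" for k in range(5)]
        genotypes = {s: GenotypeCall(gt=HOM_ALT) for s in carriers}
        genotypes["other"] = GenotypeCall(gt=HET)
        v = mkvar(chrom="2", pos=234183368, genotypes=genotypes)
        table = known_variant_screen([v], [("2", 234183368, "A", "G", "T300A")],
                                     carriers + ["other"])
        assert (table["genotype"] == HOM_ALT).sum() == 8

    def test_empty_panel_empty_table(self):
        assert known_variant_screen([mkvar()], [], ["S1"]).empty


class TestCascadeProperties:
    def test_cascade_is_idempotent(self):
        ped = family_fixtures()["AM-CD"]
        records, _, _ = generate_variant_table(
            ped, SynthConfig(seed=13), [CandidateSpec("CAND", ("V-1", "V-3"))],
            [DecoySpec(k, ("V-1", "V-3")) for k in ("genotype_gq", "no_call_rate")],
            control_ids=("V-2", "V-4"),
        )
        once = no_call_filter(apply_genotype_filters(site_filter(records)))
        twice = no_call_filter(apply_genotype_filters(site_filter(once)))
        assert [v.key for v in once] == [v.key for v in twice]
        for a, b in zip(once, twice):
            assert a.genotypes == b.genotypes

    def test_vcf_and_annotation_round_trip(self, tmp_path):
        ped = family_fixtures()["AM-CD"]
        records, ann, _ = generate_variant_table(
            ped, SynthConfig(seed=14), [CandidateSpec("CAND", ("V-1", "V-3"))], [],
            n_background=10,
        )
        samples = [i.id for i in ped]
        path = tmp_path / "fam.vcf"
        write_vcf(records, path, samples)
        back = read_vcf(path, annotations=ann)
        assert len(back) == len(records)
        by_key = {v.key: v for v in back}
        for v in records:
            w = by_key[v.key]
            assert w.gene == v.gene and w.consequence == v.consequence
            assert w.maf == v.maf
            assert {s: c.gt for s, c in w.genotypes.items()} == {
                s: c.gt for s, c in v.genotypes.items()
            }
            assert w.tranche_sensitivity == pytest.approx(v.tranche_sensitivity)
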