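import itertools

import pytest

from hap_panel.family import (BIALLELIC_HOM, COMPOUND_HET, DIGENIC,
                              SINGLE_HET, Individual, Pedigree,
                              PedigreeError, detect_biallelic,
                              detect_cooccurrence, phase_compound_het,
                              read_ped, segregation_check)
from hap_panel.variants import VariantRecord
from tests._oracles import phase_oracle


def _rec(sample, gene, pos, zyg="het", cls="VUS"):
    r = VariantRecord(chrom="panel_ref", pos=pos, ref="A", alt="G",
                      sample_id=sample, gene=gene, zygosity=zyg)
    r.acmg_class = cls
    return r


class TestCooccurrence:
    def test_fixture_yields_exactly_the_five_families(self, fixture_run):
        dig = [f for f in fixture_run["findings"] if f.kind == DIGENIC]
        assert sorted(f.patient_id for f in dig) == [
            "HTP070", "HTP081", "HTP466", "HTP474", "HTP611"]
        by_id = {f.patient_id: f for f in dig}
        assert by_id["HTP474"].genes == ["ABCC8", "SARS2"]
        assert by_id["HTP081"].genes == ["BMPR2", "NOTCH3"]  # CNV + SNV

    def test_single_variant_patient_has_no_finding(self):
        assert detect_cooccurrence([_rec("p1", "BMPR2", 100)]) == []

    def test_two_variants_same_gene_is_not_digenic(self):
        recs = [_rec("p1", "EIF2AK4", 100), _rec("p1", "EIF2AK4", 200)]
        assert detect_cooccurrence(recs) == []

    def test_variants_sorted_by_gene(self):
        recs = [_rec("p1", "TBX4", 500, cls="P"),
                _rec("p1", "ABCC8", 100)]
        (f,) = detect_cooccurrence(recs)
        assert f.genes == ["ABCC8", "TBX4"]
        assert f.variants[0].gene == "ABCC8"


class TestPhaseLogic:
    def test_one_variant_per_parent_is_trans(self):
        kind, seg = phase_compound_het(((), ()), 1, 0, 0, 1)
        assert (kind, seg) == (COMPOUND_HET, "consistent")

    def test_both_from_mother_is_cis(self):
        kind, seg = phase_compound_het(((), ()), 0, 1, 0, 1)
        assert (kind, seg) == (SINGLE_HET, "consistent")

    def test_no_parents_is_untested(self):
        kind, seg = phase_compound_het(((), ()), None, None, None, None)
        assert (kind, seg) == (COMPOUND_HET, "untested")

    def test_allele_absent_from_both_parents_is_inconsistent(self):
        kind, seg = phase_compound_het(((), ()), 0, 0, 0, 1)
        assert seg == "inconsistent"

    def test_exhaustive_trio_agreement_with_enumeration_oracle(self):
        """All parental genotype combinations for a double-het child."""
        for f1, f2, m1, m2 in itertools.product((0, 1, 2), repeat=4):
            got = phase_compound_het(((), ()), f1, m1, f2, m2)
            assert got == phase_oracle(f1, m1, f2, m2), (f1, f2, m1, m2)


class TestBiallelic:
    def _trio_ped(self, v1, v2, fa_gt, mo_gt):
        ped = Pedigree("F1")
        ped.add(Individual("fa", None, None, "male", False))
        ped.add(Individual("mo", None, None, "female", False))
        ped.add(Individual("kid", "fa", "mo", "unknown", True))
        ped.set_genotype("fa", v1.key, fa_gt[0])
        ped.set_genotype("fa", v2.key, fa_gt[1])
        ped.set_genotype("mo", v1.key, mo_gt[0])
        ped.set_genotype("mo", v2.key, mo_gt[1])
        return ped

    def test_compound_het_with_parental_carriers(self):
        v1 = _rec("kid", "EIF2AK4", 100, cls="P")
        v2 = _rec("kid", "EIF2AK4", 300, cls="P")
        ped = self._trio_ped(v1, v2, (1, 0), (0, 1))
        (f,) = detect_biallelic([v1, v2], ped)
        assert f.kind == COMPOUND_HET and f.segregation == "consistent"

    def test_homozygous_founder_case(self):
        v = _rec("kid", "EIF2AK4", 100, zyg="hom", cls="P")
        (f,) = detect_biallelic([v])
        assert f.kind == BIALLELIC_HOM

    def test_both_hets_from_one_parent_is_cis(self):
        v1 = _rec("kid", "EIF2AK4", 100)
        v2 = _rec("kid", "EIF2AK4", 300)
        ped = self._trio_ped(v1, v2, (0, 0), (1, 1))
        (f,) = detect_biallelic([v1, v2], ped)
        assert f.kind == SINGLE_HET
        assert any("cis" in n for n in f.notes)

    def test_without_parents_phase_is_untested(self):
        v1 = _rec("kid", "EIF2AK4", 100)
        v2 = _rec("kid", "EIF2AK4", 300)
        (f,) = detect_biallelic([v1, v2])
        assert f.kind == COMPOUND_HET and f.segregation == "untested"

    def test_other_genes_are_ignored(self):
        recs = [_rec("kid", "BMPR2", 100), _rec("kid", "BMPR2", 300)]
        assert detect_biallelic(recs, gene="EIF2AK4") == []

    def test_fixture_pvod_cases(self, fixture_run):
        kinds = {(f.patient_id, f.kind, f.segregation)
                 for f in fixture_run["findings"] if f.kind != DIGENIC}
        assert ("PVOD_SIB1", COMPOUND_HET, "consistent") in kinds
        assert ("PVOD_SIB2", COMPOUND_HET, "consistent") in kinds
        assert ("PVOD_HOM1", BIALLELIC_HOM, "untested") in kinds


class TestSegregation:
    def test_unaffected_carrier_mother_is_consistent_with_note(self):
        v = _rec("kid", "BMPR2", 100, cls="P")
        ped = Pedigree("F1")
        ped.add(Individual("mo", None, None, "female", False))
        ped.add(Individual("kid", None, "mo", "unknown", True))
        ped.set_genotype("mo", v.key, 1)
        ped.set_genotype("kid", v.key, 1)
        from hap_panel.family import InheritanceFinding
        f = InheritanceFinding("kid", "single_het", [v], ["BMPR2"])
        f = segregation_check(f, ped)
        assert f.segregation == "consistent"
        assert any("penetrance" in n for n in f.notes)

    def test_hom_child_of_two_ref_parents_is_inconsistent(self):
        v = _rec("kid", "EIF2AK4", 100, zyg="hom")
        ped = Pedigree("F1")
        ped.add(Individual("fa", None, None, "male", False))
        ped.add(Individual("mo", None, None, "female", False))
        ped.add(Individual("kid", "fa", "mo", "unknown", True))
        for iid, gt in (("fa", 0), ("mo", 0), ("kid", 2)):
            ped.set_genotype(iid, v.key, gt)
        from hap_panel.family import InheritanceFinding
        f = InheritanceFinding("kid", BIALLELIC_HOM, [v], ["EIF2AK4"])
        assert segregation_check(f, ped).segregation == "inconsistent"

    def test_no_relative_genotypes_is_untested(self):
        v = _rec("kid", "BMPR2", 100)
        ped = Pedigree("F1")
        ped.add(Individual("kid", None, None, "unknown", True))
        from hap_panel.family import InheritanceFinding
        f = InheritanceFinding("kid", "single_het", [v], ["BMPR2"])
        assert segregation_check(f, ped).segregation == "untested"


class TestPedigreeIO:
    def test_read_ped_round(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text("F1 fa 0 0 1 1\nF1 mo 0 0 2 1\nF1 kid fa mo 1 2\n")
        peds = read_ped(p)
        assert set(peds) == {"F1"}
        kid = peds["F1"].members["kid"]
        assert kid.father == "fa" and kid.affected and kid.sex == "male"

    def test_unknown_parent_reference_errors(self, tmp_path):
        p = tmp_path / "fam.ped"
        p.write_text("F1 kid fa mo 1 2\n")
        with pytest.raises(PedigreeError):
            read_ped(p)

    def test_self_ancestry_detected(self):
        ped = Pedigree("F1")
        ped.add(Individual("a", "b", None))
        ped.add(Individual("b", "a", None))
        with pytest.raises(PedigreeError):
            ped.validate()
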