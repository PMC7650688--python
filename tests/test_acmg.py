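import itertools

import pytest

from hap_panel.acmg import (ALL_CODES, EvidenceConfig, EvidenceError,
                            EvidenceSet, combine_evidence, default_evidence)
from tests._oracles import acmg_oracle


class TestCombining:
    @pytest.mark.parametrize("codes,expected", [
        (set(), "VUS"),
        ({"PVS1", "PS3"}, "P"),
        ({"PVS1", "PM2"}, "LP"),
        ({"BA1", "PM2"}, "VUS"),            # conflicting evidence
        ({"PM2", "PP3"}, "VUS"),
        ({"PS1", "PS2"}, "P"),
        ({"PVS1", "PM2", "PP5"}, "P"),
        ({"PM1", "PM2", "PM4"}, "LP"),
        ({"BA1"}, "B"),
        ({"BS1", "BS2"}, "B"),
        ({"BS1", "BP4"}, "LB"),
        ({"BP4", "BP7"}, "LB"),
        ({"PS1", "PM1", "PM2", "PM4"}, "P"),
    ])
    def test_spot_checks_against_the_combining_table(self, codes, expected):
        assert combine_evidence(EvidenceSet(frozenset(codes))) == expected
        assert acmg_oracle(frozenset(codes)) == expected

    def test_unknown_code_is_an_error(self):
        with pytest.raises(EvidenceError):
            combine_evidence(EvidenceSet(frozenset({"PX9"})))

    def test_exhaustive_agreement_small_subsets(self):
        """Engine equals the enumeration oracle on all subsets of size <=2."""
        for sub in itertools.chain(
                itertools.combinations(ALL_CODES, 1),
                itertools.combinations(ALL_CODES, 2)):
            codes = frozenset(sub)
            assert combine_evidence(EvidenceSet(codes)) == acmg_oracle(codes)

    def test_adding_pathogenic_evidence_never_moves_toward_benign(self):
        order = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}
        base_sets = [frozenset(), {"PM2"}, {"PM2", "PP3"}, {"PVS1"},
                     {"PS1", "PM1"}]
        extras = ["PVS1", "PS3", "PM5", "PP2"]
        for base in base_sets:
            base = frozenset(base)
            v0 = combine_evidence(EvidenceSet(base))
            for extra in extras:
                if extra in base:
                    continue
                v1 = combine_evidence(EvidenceSet(base | {extra}))
                assert order[v1] >= order[v0], (base, extra)

    def test_strength_override_demotes_pvs1(self):
        ev = EvidenceSet(frozenset({"PVS1", "PM2"}),
                         strength_overrides={"PVS1": "strong"})
        assert combine_evidence(ev) == "LP"  # 1 strong + 1 moderate

    def test_override_must_reference_present_code(self):
        with pytest.raises(EvidenceError):
            EvidenceSet(frozenset({"PM2"}), strength_overrides={"PVS1": "strong"})


class TestDefaultEvidence:
    def test_truncating_in_established_gene_gets_pvs1_pm2(self, fixture_run):
        rec = next(r for r in fixture_run["candidates"]
                   if r.gene == "TBX4" and r.hgvs.start.pos == 1018)
        ev = default_evidence(rec, fixture_run["fixture"].panel)
        assert {"PVS1", "PM2"} <= set(ev.codes)
        assert rec.acmg_class == "P"

    def test_rare_missense_mixed_predictors_is_vus(self, fixture_run):
        rec = next(r for r in fixture_run["candidates"]
                   if r.gene == "NOTCH3" and r.hgvs.start.pos == 181)
        ev = default_evidence(rec, fixture_run["fixture"].panel)
        assert set(ev.codes) <= {"PM2", "PP3"}
        assert rec.acmg_class == "VUS"

    def test_common_variant_is_benign(self, panel):
        from hap_panel.annotate import AnnotationBundle
        from hap_panel.variants import VariantRecord

        rec = VariantRecord(chrom="panel_ref", pos=10, ref="A", alt="G",
                            sample_id="S", gene="BMPR2")
        rec.annotations = AnnotationBundle(af_sources={"g": 0.1})
        ev = default_evidence(rec, panel)
        assert "BA1" in ev.codes
        assert combine_evidence(ev) == "B"

    def test_unannotated_record_errors(self, panel):
        from hap_panel.variants import VariantRecord

        rec = VariantRecord(chrom="panel_ref", pos=10, ref="A", alt="G",
                            sample_id="S")
        with pytest.raises(EvidenceError):
            default_evidence(rec, panel)

    def test_segregation_support_adds_pp1(self, fixture_run):
        rec = next(r for r in fixture_run["candidates"]
                   if r.gene == "NOTCH3" and r.hgvs.start.pos == 181)
        ev = default_evidence(rec, fixture_run["fixture"].panel,
                              cohort_context={"segregation_support": True})
        assert "PP1" in ev.codes

    def test_truncating_in_candidate_gene_has_no_pvs1(self, fixture_run):
        rec = next(r for r in fixture_run["candidates"]
                   if r.gene == "ABCC8" and r.hgvs.start.pos == 3288)
        ev = default_evidence(rec, fixture_run["fixture"].panel)
        assert "PVS1" not in ev.codes


class TestFixtureReproduction:
    def test_printed_truncating_pathogenic_rows_reproduce(self, fixture_run):
        """Rows printed P with truncating consequences classify P."""
        for r in fixture_run["candidates"]:
            if r.printed_class == "P" and r.annotations.consequence in (
                    "stop_gained", "frameshift", "splice_canonical"):
                assert r.acmg_class == "P", (r.gene, r.hgvs.cdna)

    def test_printed_vus_missense_rows_reproduce(self, fixture_run):
        for r in fixture_run["candidates"]:
            if r.printed_class == "VUS" and \
                    r.annotations.consequence == "missense":
                assert r.acmg_class == "VUS", (r.gene, r.hgvs.cdna)

    def test_mismatches_are_the_documented_ones(self, fixture_run):
        mismatches = {
            (r.gene, r.hgvs.cdna)
            for r in fixture_run["candidates"]
            if r.printed_class and r.printed_class != r.acmg_class
        }
        assert mismatches == {
            ("BMPR2", "c.77-5_77-2delTTTA"),   # printed P, splice-region del
            ("ABCC8", "c.3976G>A"),            # printed LP, defaults give VUS
            ("GDF2", "c.642G>A"),              # table VUS vs truncating LP
            ("EIF2AK4", "c.3344C>T"),          # founder missense printed P
        }
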