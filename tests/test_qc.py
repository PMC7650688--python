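import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hap_panel.qc import (QcConfig, SampleQcReport, coverage_fraction,
                          qc_gate, titv_ratio)
from hap_panel.variants import VariantRecord


def _snv(ref, alt, zyg="het"):
    return VariantRecord(chrom="panel_ref", pos=1, ref=ref, alt=alt,
                         sample_id="S", zygosity=zyg)


class TestCoverageFraction:
    def test_all_above_threshold(self):
        assert coverage_fraction([25] * 10, 20) == 1.0

    def test_half_covered(self):
        assert coverage_fraction([10] * 5 + [30] * 5, 20) == 0.5

    def test_threshold_is_inclusive(self):
        assert coverage_fraction([20], 20) == 1.0

    def test_empty_targets_error(self):
        with pytest.raises(ValueError):
            coverage_fraction([], 20)

    def test_weighted_equals_expanded(self):
        depths, lengths = [25.0, 5.0, 30.0], [10, 30, 60]
        expanded = [d for d, n in zip(depths, lengths) for _ in range(n)]
        assert coverage_fraction(depths, 20, weights=lengths) == \
            pytest.approx(coverage_fraction(expanded, 20))

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=50),
           st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_non_increasing_in_threshold(self, depths, threshold):
        assert coverage_fraction(depths, threshold) >= \
            coverage_fraction(depths, threshold + 1)


class TestTiTv:
    def test_four_transitions_one_transversion(self):
        recs = [_snv("A", "G"), _snv("G", "A"), _snv("C", "T"),
                _snv("T", "C"), _snv("A", "C")]
        tk, tn = titv_ratio(recs, [True] * 5)
        assert tk == 4.0 and tn is None

    def test_zero_transversions_is_undefined_not_infinite(self):
        recs = [_snv("A", "G"), _snv("C", "T")]
        tk, tn = titv_ratio(recs, [False, False])
        assert tk is None and tn is None

    def test_indels_are_ignored(self):
        recs = [_snv("A", "G"),
                VariantRecord(chrom="panel_ref", pos=1, ref="AT", alt="A",
                              sample_id="S"),
                _snv("A", "T")]
        tk, tn = titv_ratio(recs, [True, True, True])
        assert tk == 1.0

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("T", "C")] * 4
        flags = [bool(b) for b in rng.integers(0, 2, size=len(pairs))]
        recs = [_snv(r, a) for r, a in pairs]
        base = titv_ratio(recs, flags)
        order = rng.permutation(len(recs))
        assert titv_ratio([recs[i] for i in order],
                          [flags[i] for i in order]) == base

    def test_simulated_strata_recover_the_generating_odds(self):
        """Binomial draws at the typical coding-panel odds land near them."""
        from hap_panel.simulate import simulate_titv_records

        rng = np.random.default_rng(99)
        known = simulate_titv_records(10_000, 3.2, rng)
        novel = simulate_titv_records(10_000, 2.9, rng)
        tk, _ = titv_ratio(known, [True] * len(known))
        _, tn = titv_ratio(novel, [False] * len(novel))
        assert abs(tk - 3.2) <= 0.15
        assert abs(tn - 2.9) <= 0.15


class TestQcGate:
    def test_coverage_breach_fails_with_reason(self):
        r = qc_gate(SampleQcReport("s1", fraction_at_20x=0.94))
        assert not r.passed
        assert any("coverage" in reason for reason in r.failure_reasons)

    def test_nominal_sample_passes(self):
        r = qc_gate(SampleQcReport("s1", fraction_at_20x=0.99,
                                   on_target_fraction=0.85, titv_known=3.1))
        assert r.passed and r.failure_reasons == []

    def test_each_breach_appends_one_reason(self):
        r = qc_gate(SampleQcReport("s1", fraction_at_20x=0.80,
                                   on_target_fraction=0.50, titv_known=1.0))
        assert len(r.failure_reasons) == 3

    def test_titv_band_needs_enough_snvs(self):
        r = qc_gate(SampleQcReport("s1", fraction_at_20x=0.99,
                                   titv_known=1.0, n_snvs_known=10))
        assert r.passed  # too few SNVs for the band to be meaningful
        r2 = qc_gate(SampleQcReport("s1", fraction_at_20x=0.99,
                                    titv_known=1.0, n_snvs_known=200))
        assert not r2.passed

    def test_gate_is_deterministic_and_partitions(self):
        reports = [SampleQcReport(f"s{i}", fraction_at_20x=f)
                   for i, f in enumerate([0.99, 0.94, 0.95, 0.90])]
        gated = [qc_gate(r) for r in reports]
        assert [r.passed for r in gated] == [True, False, True, False]
        assert all(r.passed == (not r.failure_reasons) for r in gated)

    def test_proportions_validated(self):
        with pytest.raises(ValueError):
            SampleQcReport("s1", fraction_at_20x=1.2)
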