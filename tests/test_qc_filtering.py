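"""Sample QC gates and DNA/RNA retention filters."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from metex14 import (FilterConfig, FusionCall, SampleQcMetrics, ValidationError,
                     VariantCall, af_depth_consistent, classify_variant_type,
                     filter_variants, passes_dna_filters, passes_rna_filter,
                     sample_qc_pass)


def make_variant(**kw) -> VariantCall:
    base = dict(patient_id="P1", chromosome="7", pos=116412044, ref="G", alt="T",
                allele_frequency=0.2, site_depth=500, alt_reads=100,
                quality_phred=30.0, gene="MET")
    base.update(kw)
    return VariantCall(**base)


class TestSampleQc:
    def test_all_gates_at_threshold_pass(self):
        ok, failed = sample_qc_pass(SampleQcMetrics("P1", 240, 60, 20_000, 3))
        assert ok and failed == []

    @pytest.mark.parametrize("metrics,expect_failed", [
        ((239, 99, 10**6, 5), ["median_reads_per_amplicon"]),
        ((1000, 60, 19_999, 3), ["rna_mapped_reads"]),
        ((241, 59.9, 20_001, 3), ["pct_aligned_reads"]),
        ((1000, 90, 10**6, 2), ["expression_controls_detected"]),
        ((239, 59, 19_999, 2), ["median_reads_per_amplicon", "pct_aligned_reads",
                                "rna_mapped_reads", "expression_controls_detected"]),
    ])
    def test_single_gate_below_bound_fails_by_name(self, metrics, expect_failed):
        ok, failed = sample_qc_pass(SampleQcMetrics("P1", *metrics))
        assert not ok and failed == expect_failed

    def test_missing_metric_fails_with_missing_gate(self):
        ok, failed = sample_qc_pass(SampleQcMetrics("P1", 500, None, 30_000, 4))
        assert not ok and failed == ["missing:pct_aligned_reads"]


class TestVariantType:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", "SNV"), ("GATTACA", "G", "INDEL"), ("A", "ATT", "INDEL"),
        ("AT", "GC", "INDEL"),
    ])
    def test_classification(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) == expected

    def test_empty_allele_rejected(self):
        with pytest.raises(ValidationError):
            classify_variant_type("A", "")


class TestDnaFilters:
    def test_snv_at_all_boundaries_kept(self):
        v = make_variant(allele_frequency=0.05, site_depth=60, alt_reads=12,
                         quality_phred=7)
        keep, failed = passes_dna_filters(v)
        assert keep and failed == []

    @pytest.mark.parametrize("kw,expect_rule", [
        (dict(allele_frequency=0.049), "allele_frequency"),
        (dict(alt_reads=9), "alt_reads"),
        (dict(site_depth=49, alt_reads=49), "site_depth"),
        (dict(quality_phred=5.9), "quality"),
    ])
    def test_single_rule_failures_enumerated(self, kw, expect_rule):
        keep, failed = passes_dna_filters(make_variant(**kw))
        assert not keep and failed == [expect_rule]

    def test_indel_has_its_own_af_and_quality_bounds(self):
        indel = dict(ref="GAT", alt="G")
        keep, _ = passes_dna_filters(make_variant(allele_frequency=0.07,
                                                  quality_phred=20, **indel))
        assert keep
        keep, failed = passes_dna_filters(make_variant(allele_frequency=0.069,
                                                       quality_phred=20, **indel))
        assert not keep and failed == ["allele_frequency"]
        keep, failed = passes_dna_filters(make_variant(allele_frequency=0.2,
                                                       quality_phred=19, **indel))
        assert not keep and failed == ["quality"]

    @given(
        af=st.floats(0, 1), depth=st.integers(0, 2000),
        frac=st.floats(0, 1), phred=st.floats(0, 60),
        is_indel=st.booleans(),
        bumps=st.tuples(*[st.floats(0, 0.1)] * 2 + [st.integers(0, 20)] * 2
                        + [st.floats(0, 10)] * 2),
    )
    def test_raising_thresholds_is_monotone(self, af, depth, frac, phred,
                                            is_indel, bumps):
        """A variant dropped under a config stays dropped when any threshold rises."""
        alt = int(depth * frac)
        v = make_variant(ref="GA" if is_indel else "G", allele_frequency=af,
                         site_depth=depth, alt_reads=alt, quality_phred=phred)
        loose = FilterConfig()
        strict = FilterConfig(
            min_af_snv=loose.min_af_snv + bumps[0],
            min_af_indel=loose.min_af_indel + bumps[1],
            min_alt_reads=loose.min_alt_reads + bumps[2],
            min_site_depth=loose.min_site_depth + bumps[3],
            min_phred_snv=loose.min_phred_snv + bumps[4],
            min_phred_indel=loose.min_phred_indel + bumps[5],
        )
        keep_strict, _ = passes_dna_filters(v, strict)
        keep_loose, _ = passes_dna_filters(v, loose)
        assert not (keep_strict and not keep_loose)


class TestRnaFilter:
    @pytest.mark.parametrize("reads,keep", [(21, True), (20, False), (0, False),
                                            (120, True)])
    def test_strictly_more_than_twenty(self, reads, keep):
        f = FusionCall("P1", "MET-MET.M13M15", 13, 15, reads)
        assert passes_rna_filter(f) is keep


class TestAuditAndConsistency:
    def test_af_depth_consistency_flag(self):
        assert af_depth_consistent(make_variant(allele_frequency=0.2,
                                                site_depth=500, alt_reads=100))
        assert not af_depth_consistent(make_variant(allele_frequency=0.25,
                                                    site_depth=500, alt_reads=100))

    def test_audit_retains_dropped_records_with_reasons(self):
        good = make_variant()
        bad = make_variant(patient_id="P2", allele_frequency=0.01, alt_reads=5)
        kept, audit = filter_variants([good, bad])
        assert kept == [good]
        assert len(audit) == 2
        row = audit[audit.patient_id == "P2"].iloc[0]
        assert not row.kept
        assert row.failed_rules == "allele_frequency;alt_reads"

    def test_filtering_is_order_independent_and_idempotent(self):
        vs = [make_variant(patient_id=f"P{i}", allele_frequency=0.01 * i)
              for i in range(1, 12)]
        kept_fwd, _ = filter_variants(vs)
        kept_rev, _ = filter_variants(vs[::-1])
        assert sorted(v.patient_id for v in kept_fwd) == \
            sorted(v.patient_id for v in kept_rev)
        kept_again, _ = filter_variants(kept_fwd)
        assert kept_again == kept_fwd

    def test_hotspot_allowlist_restricts_positions(self):
        v = make_variant()
        kept, audit = filter_variants([v], hotspot_positions={("7", 116412044)})
        assert kept == [v]
        kept, audit = filter_variants([v], hotspot_positions={("7", 1)})
        assert kept == [] and audit.iloc[0].failed_rules == "hotspot"


class TestVariantCallInvariants:
    @pytest.mark.parametrize("kw", [
        dict(alt_reads=501),              # alt reads exceed depth
        dict(allele_frequency=1.5),
        dict(ref=""),
        dict(quality_phred=-1.0),
    ])
    def test_invalid_records_rejected(self, kw):
        with pytest.raises(ValidationError):
            make_variant(**kw)

    def test_variant_class_derived_from_alleles(self):
        assert make_variant().variant_class == "SNV"
        assert make_variant(ref="GA", alt="G").variant_class == "INDEL"
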