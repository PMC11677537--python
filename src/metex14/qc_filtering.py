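"""Sample-level QC gates and DNA/RNA variant-retention filters.

The pipeline starts at called variants (DNA small variants from a targeted
amplicon panel) and fusion read counts (RNA exon13-exon15 junction reads);
this module decides which records survive into the diagnostic analysis.
Every "minimum"-phrased threshold is inclusive (>=); the single fusion-read
retention rule is exclusive (strictly more than 20 reads).  Dropped records
are never discarded silently: filtering returns an audit trail listing the
rule(s) each record failed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "VariantCall",
    "FusionCall",
    "SampleQcMetrics",
    "QcThresholds",
    "FilterConfig",
    "sample_qc_pass",
    "classify_variant_type",
    "passes_dna_filters",
    "passes_rna_filter",
    "af_depth_consistent",
    "filter_variants",
    "filter_fusions",
    "read_fusion_table",
    "write_fusion_table",
    "read_qc_table",
]

METEX14_FIVE_PRIME_EXON = 13
METEX14_THREE_PRIME_EXON = 15


@dataclass(frozen=True)
class VariantCall:
    """One DNA small-variant observation in one patient."""

    patient_id: str
    chromosome: str
    pos: int
    ref: str
    alt: str
    allele_frequency: float
    site_depth: int
    alt_reads: int
    quality_phred: float
    gene: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt alleles must be non-empty")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValidationError(f"allele frequency {self.allele_frequency} outside [0,1]")
        if self.site_depth < 0 or self.alt_reads < 0:
            raise ValidationError("read counts must be non-negative")
        if self.alt_reads > self.site_depth:
            raise ValidationError(
                f"alt_reads {self.alt_reads} exceeds site_depth {self.site_depth}")
        if self.quality_phred < 0:
            raise ValidationError("quality_phred must be non-negative")

    @property
    def variant_class(self) -> str:
        return classify_variant_type(self.ref, self.alt)


@dataclass(frozen=True)
class FusionCall:
    """One RNA fusion observation (junction read count) in one patient."""

    patient_id: str
    fusion_id: str
    five_prime_exon: int
    three_prime_exon: int
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValidationError("read_count must be non-negative")

    @property
    def is_metex14(self) -> bool:
        return (self.five_prime_exon == METEX14_FIVE_PRIME_EXON
                and self.three_prime_exon == METEX14_THREE_PRIME_EXON)


@dataclass(frozen=True)
class SampleQcMetrics:
    """Per-sample sequencing QC metrics; ``None`` marks a missing metric."""

    patient_id: str
    median_reads_per_amplicon: float | None
    pct_aligned_reads: float | None
    rna_mapped_reads: int | None
    expression_controls_detected: int | None


@dataclass(frozen=True)
class QcThresholds:
    """Sample-level QC gates; all inclusive minima."""

    min_median_reads_per_amplicon: float = 240.0
    min_pct_aligned_reads: float = 60.0
    min_rna_mapped_reads: int = 20_000
    min_expression_controls: int = 3


@dataclass(frozen=True)
class FilterConfig:
    """Variant-retention thresholds.

    All DNA thresholds are inclusive minima; the fusion-read rule keeps a
    record only when ``read_count`` strictly exceeds
    ``min_fusion_reads_exclusive``.
    """

    min_af_snv: float = 0.05
    min_af_indel: float = 0.07
    min_alt_reads: int = 10
    min_site_depth: int = 50
    min_phred_snv: float = 6.0
    min_phred_indel: float = 20.0
    min_fusion_reads_exclusive: int = 20

    def __post_init__(self) -> None:
        for name in ("min_af_snv", "min_af_indel", "min_alt_reads", "min_site_depth",
                     "min_phred_snv", "min_phred_indel", "min_fusion_reads_exclusive"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def sample_qc_pass(m: SampleQcMetrics,
                   thresholds: QcThresholds | None = None) -> tuple[bool, list[str]]:
    """Evaluate the four sample QC gates; returns (passed, failed gate names).

    A missing metric fails its gate with reason ``"missing:<gate>"``.
    """
    t = thresholds or QcThresholds()
    gates = [
        ("median_reads_per_amplicon", m.median_reads_per_amplicon,
         t.min_median_reads_per_amplicon),
        ("pct_aligned_reads", m.pct_aligned_reads, t.min_pct_aligned_reads),
        ("rna_mapped_reads", m.rna_mapped_reads, t.min_rna_mapped_reads),
        ("expression_controls_detected", m.expression_controls_detected,
         t.min_expression_controls),
    ]
    failed: list[str] = []
    for name, value, minimum in gates:
        if value is None or value != value:  # None or NaN
            failed.append(f"missing:{name}")
        elif value < minimum:
            failed.append(name)
    return (not failed, failed)


def classify_variant_type(ref: str, alt: str) -> str:
    """"SNV" when both alleles are single bases, otherwise "INDEL"."""
    if not ref or not alt:
        raise ValidationError("ref and alt alleles must be non-empty")
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"


def passes_dna_filters(v: VariantCall,
                       cfg: FilterConfig | None = None) -> tuple[bool, list[str]]:
    """Apply the DNA retention rules; returns (keep, failed rule names)."""
    cfg = cfg or FilterConfig()
    is_snv = v.variant_class == "SNV"
    min_af = cfg.min_af_snv if is_snv else cfg.min_af_indel
    min_phred = cfg.min_phred_snv if is_snv else cfg.min_phred_indel
    failed: list[str] = []
    if v.allele_frequency < min_af:
        failed.append("allele_frequency")
    if v.alt_reads < cfg.min_alt_reads:
        failed.append("alt_reads")
    if v.site_depth < cfg.min_site_depth:
        failed.append("site_depth")
    if v.quality_phred < min_phred:
        failed.append("quality")
    return (not failed, failed)


def passes_rna_filter(f: FusionCall, cfg: FilterConfig | None = None) -> bool:
    """Keep a fusion record only with strictly more than the threshold reads."""
    cfg = cfg or FilterConfig()
    return f.read_count > cfg.min_fusion_reads_exclusive


def af_depth_consistent(v: VariantCall, tolerance: float = 0.01) -> bool:
    """Whether the reported AF agrees with alt_reads/site_depth within tolerance."""
    if v.site_depth == 0:
        return True
    return abs(v.allele_frequency - v.alt_reads / v.site_depth) <= tolerance


def filter_variants(variants: Iterable[VariantCall],
                    cfg: FilterConfig | None = None,
                    hotspot_positions: set[tuple[str, int]] | None = None,
                    ) -> tuple[list[VariantCall], pd.DataFrame]:
    """Filter DNA variants, returning kept calls and a full audit table.

    ``hotspot_positions`` is an optional allow-list of (chromosome, pos);
    when given, variants outside it fail rule "hotspot".  The audit table
    has one row per input variant with its decision, failed rules, and an
    AF/depth consistency flag; it is idempotent and order-independent.
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantCall] = []
    rows = []
    for v in variants:
        ok, failed = passes_dna_filters(v, cfg)
        if hotspot_positions is not None and (str(v.chromosome), v.pos) not in hotspot_positions:
            ok, failed = False, failed + ["hotspot"]
        if ok:
            kept.append(v)
        rows.append({
            "patient_id": v.patient_id, "chromosome": v.chromosome, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "gene": v.gene,
            "variant_class": v.variant_class, "kept": ok,
            "failed_rules": ";".join(failed),
            "af_depth_consistent": af_depth_consistent(v),
        })
    audit = pd.DataFrame(rows, columns=[
        "patient_id", "chromosome", "pos", "ref", "alt", "gene", "variant_class",
        "kept", "failed_rules", "af_depth_consistent"])
    return kept, audit


def filter_fusions(fusions: Iterable[FusionCall],
                   cfg: FilterConfig | None = None,
                   metex14_only: bool = True) -> list[FusionCall]:
    """Retain fusion records passing the read-count rule (optionally METex14 only)."""
    cfg = cfg or FilterConfig()
    return [f for f in fusions
            if passes_rna_filter(f, cfg) and (f.is_metex14 or not metex14_only)]


# ---------------------------------------------------------------------------
# Tabular I/O (tab-separated; '#' lines are comments)

_FUSION_COLS = ["patient_id", "fusion_id", "five_prime_exon", "three_prime_exon",
                "read_count"]


def read_fusion_table(path) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})
    missing = set(_FUSION_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"fusion table missing columns: {sorted(missing)}")
    return [FusionCall(r.patient_id, r.fusion_id, int(r.five_prime_exon),
                       int(r.three_prime_exon), int(r.read_count))
            for r in df.itertuples()]


def write_fusion_table(fusions: Sequence[FusionCall], path, header_comment: str = "") -> None:
    df = pd.DataFrame([{c: getattr(f, c) for c in _FUSION_COLS} for f in fusions],
                      columns=_FUSION_COLS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_qc_table(path) -> list[SampleQcMetrics]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})

    def _opt(row, col, cast):
        val = getattr(row, col, None)
        if val is None or val != val:
            return None
        return cast(val)

    return [SampleQcMetrics(
        patient_id=r.patient_id,
        median_reads_per_amplicon=_opt(r, "median_reads_per_amplicon", float),
        pct_aligned_reads=_opt(r, "pct_aligned_reads", float),
        rna_mapped_reads=_opt(r, "rna_mapped_reads", int),
        expression_controls_detected=_opt(r, "expression_controls_detected", int),
    ) for r in df.itertuples()]
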