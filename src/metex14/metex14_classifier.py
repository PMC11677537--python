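"""Dual-evidence METex14 diagnostic classification and RNA/DNA concordance.

A patient is diagnosed from two evidence streams: the RNA exon13-exon15
fusion read count, and filter-passing DNA variants falling in the exon 14
splice acceptor/donor windows.  The assay guide's positivity threshold is
at least 120 fusion reads; detected-but-sub-threshold patients (more than
20 but fewer than 120 reads) are *undetermined* unless a splice-region DNA
variant rescues the diagnosis.  DNA evidence without any retained fusion
record yields a DNA-only positive, kept distinct from RNA-confirmed
positivity in all outputs.

The concordance statistics reproduce the cohort-level analyses: Pearson
correlation of RNA reads against DNA coverage with zeros imputed for
undetected DNA (over all detected patients, and over the low-read
subgroup), the fraction of RNA-positive patients with no DNA evidence, and
the fraction of low-read patients rescued by DNA.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError
from .gene_model import GeneModel, RegionHit, SpliceWindows, build_splice_windows, \
    WindowConfig, variant_in_splice_region
from .qc_filtering import FilterConfig, FusionCall, VariantCall, filter_fusions, \
    filter_variants

__all__ = [
    "Category",
    "ClassifierConfig",
    "Metex14Call",
    "ConcordanceStats",
    "classify_metex14",
    "pearson_with_zero_imputation",
    "concordance_summary",
    "splice_window_variants",
    "dna_coverage_map",
    "classify_cohort",
    "calls_to_frame",
]


class Category(enum.Enum):
    RNA_POSITIVE = "RNA_POSITIVE"
    DNA_RESCUED = "DNA_RESCUED"
    UNDETERMINED = "UNDETERMINED"
    DNA_ONLY_POSITIVE = "DNA_ONLY_POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class ClassifierConfig:
    """Diagnostic read-count thresholds.

    ``rna_positive_threshold`` is inclusive (at least 120 reads calls the
    sample positive); ``rna_detect_threshold_exclusive`` is the strict
    retention bound below which a fusion record counts as not detected.
    ``coverage_metric`` selects which DNA read count enters the
    concordance correlation ("alt_reads" or "site_depth").
    """

    rna_positive_threshold: int = 120
    rna_detect_threshold_exclusive: int = 20
    coverage_metric: str = "alt_reads"

    def __post_init__(self) -> None:
        if not self.rna_positive_threshold > self.rna_detect_threshold_exclusive >= 0:
            raise ValidationError(
                "require rna_positive_threshold > rna_detect_threshold_exclusive >= 0")
        if self.coverage_metric not in ("alt_reads", "site_depth"):
            raise ValidationError("coverage_metric must be 'alt_reads' or 'site_depth'")


@dataclass(frozen=True)
class Metex14Call:
    """Per-patient diagnostic category with the evidence that produced it."""

    patient_id: str
    category: Category
    rna_reads: int
    dna_splice_variants: tuple[VariantCall, ...]
    rationale: str


@dataclass(frozen=True)
class ConcordanceStats:
    pearson_r_all: float
    p_value_all: float
    pearson_r_lowread: float
    p_value_lowread: float
    frac_rna_pos_dna_negative: float
    frac_lowread_dna_rescued: float
    n_rna_detected: int
    n_rna_positive: int
    n_undetermined_or_rescued: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k in ("p_value_all", "p_value_lowread"):
            d[k] = float(f"{d[k]:.3g}")  # report p-values to 3 significant digits
        return d


def classify_metex14(patient_rna: FusionCall | None,
                     dna_splice_variants: Sequence[VariantCall],
                     cfg: ClassifierConfig | None = None,
                     patient_id: str | None = None) -> Metex14Call:
    """Apply the diagnostic decision table to one patient.

    ``dna_splice_variants`` must already be filter-passing and
    splice-window-intersecting; ``patient_rna`` must be the retained fusion
    record or ``None``.  A fusion record at or below the detection bound is
    treated exactly like an absent record.
    """
    cfg = cfg or ClassifierConfig()
    reads = patient_rna.read_count if patient_rna is not None else 0
    if reads < 0:
        raise ValidationError("negative fusion read count")
    pid = patient_id or (patient_rna.patient_id if patient_rna is not None
                         else (dna_splice_variants[0].patient_id
                               if dna_splice_variants else "?"))
    has_dna = len(dna_splice_variants) > 0
    detected = reads > cfg.rna_detect_threshold_exclusive
    if detected and reads >= cfg.rna_positive_threshold:
        cat = Category.RNA_POSITIVE
        why = (f"{reads} fusion reads >= positivity threshold "
               f"{cfg.rna_positive_threshold}")
    elif detected and has_dna:
        cat = Category.DNA_RESCUED
        why = (f"{reads} fusion reads below threshold {cfg.rna_positive_threshold}; "
               f"{len(dna_splice_variants)} splice-region DNA variant(s) rescue the call")
    elif detected:
        cat = Category.UNDETERMINED
        why = (f"{reads} fusion reads below threshold {cfg.rna_positive_threshold} "
               "and no splice-region DNA variant")
    elif has_dna:
        cat = Category.DNA_ONLY_POSITIVE
        why = (f"no retained fusion record; {len(dna_splice_variants)} "
               "splice-region DNA variant(s)")
    else:
        cat = Category.NEGATIVE
        why = "no retained fusion record and no splice-region DNA variant"
    return Metex14Call(pid, cat, reads, tuple(dna_splice_variants), why)


def pearson_with_zero_imputation(
        pairs: Iterable[tuple[float, float | None]]) -> tuple[float, float]:
    """Sample Pearson r and two-sided p-value, imputing 0 for undetected DNA.

    The second member of each pair may be ``None`` (or NaN), meaning the
    DNA variant was not detected; it enters the correlation as 0 reads.
    The p-value comes from the t transform with n-2 degrees of freedom.
    """
    xs, ys = [], []
    for x, y in pairs:
        xs.append(float(x))
        if y is None or (isinstance(y, float) and math.isnan(y)):
            ys.append(0.0)
        else:
            ys.append(float(y))
    if len(xs) < 3:
        raise UndefinedCorrelationError(f"need at least 3 pairs, got {len(xs)}")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise UndefinedCorrelationError("zero variance after imputation")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def splice_window_variants(variants: Iterable[VariantCall], model: GeneModel,
                           windows: SpliceWindows) -> dict[str, list[VariantCall]]:
    """Group filter-passing variants hitting the splice windows by patient."""
    hits: dict[str, list[VariantCall]] = {}
    for v in variants:
        if str(v.chromosome) != str(model.chromosome):
            continue
        if v.gene and v.gene != model.gene_symbol:
            continue
        region = variant_in_splice_region(v.chromosome, v.pos, v.ref, v.alt, windows)
        if region is not RegionHit.NONE:
            hits.setdefault(v.patient_id, []).append(v)
    return hits


def dna_coverage_map(splice_hits: Mapping[str, Sequence[VariantCall]],
                     metric: str = "alt_reads") -> dict[str, int]:
    """Per-patient DNA coverage for the concordance correlation.

    The best (maximum) splice-window variant per patient is used; patients
    absent from the map are treated as DNA-undetected (0) downstream.
    """
    return {pid: max(getattr(v, metric) for v in vs)
            for pid, vs in splice_hits.items() if vs}


def concordance_summary(calls: Sequence[Metex14Call],
                        dna_coverage: Mapping[str, float],
                        lowread_denominator: int | None = None) -> ConcordanceStats:
    """Cohort RNA/DNA concordance over all fusion-detected patients.

    ``lowread_denominator`` optionally overrides the denominator of the
    rescued fraction (reported cohorts sometimes quote percentages against
    a slightly different subgroup size; the override makes the printed
    arithmetic reproducible while counts stay as observed).
    """
    detected = [c for c in calls if c.category in
                (Category.RNA_POSITIVE, Category.DNA_RESCUED, Category.UNDETERMINED)]
    positives = [c for c in detected if c.category is Category.RNA_POSITIVE]
    lowread = [c for c in detected if c.category is not Category.RNA_POSITIVE]

    def cov(c: Metex14Call) -> float | None:
        return dna_coverage.get(c.patient_id)

    r_all, p_all = pearson_with_zero_imputation((c.rna_reads, cov(c)) for c in detected)
    r_low, p_low = pearson_with_zero_imputation((c.rna_reads, cov(c)) for c in lowread)
    n_pos_dna_neg = sum(1 for c in positives if not c.dna_splice_variants)
    n_rescued = sum(1 for c in lowread if c.category is Category.DNA_RESCUED)
    denom_low = lowread_denominator if lowread_denominator is not None else len(lowread)
    return ConcordanceStats(
        pearson_r_all=r_all, p_value_all=p_all,
        pearson_r_lowread=r_low, p_value_lowread=p_low,
        frac_rna_pos_dna_negative=(n_pos_dna_neg / len(positives)) if positives else 0.0,
        frac_lowread_dna_rescued=(n_rescued / denom_low) if denom_low else 0.0,
        n_rna_detected=len(detected),
        n_rna_positive=len(positives),
        n_undetermined_or_rescued=len(lowread),
    )


def classify_cohort(variants: Sequence[VariantCall],
                    fusions: Sequence[FusionCall],
                    model: GeneModel,
                    window_cfg: WindowConfig | None = None,
                    filter_cfg: FilterConfig | None = None,
                    clf_cfg: ClassifierConfig | None = None,
                    patients: Sequence[str] | None = None,
                    exon_number: int = 14,
                    ) -> tuple[list[Metex14Call], dict[str, int], pd.DataFrame]:
    """Run filtering, window annotation and classification over a cohort.

    Returns (per-patient calls, per-patient DNA coverage map, filter audit
    table).  ``patients`` fixes the patient universe (so DNA/RNA-negative
    patients receive explicit NEGATIVE calls); by default it is the union
    of patients seen in either evidence stream.
    """
    filter_cfg = filter_cfg or FilterConfig()
    clf_cfg = clf_cfg or ClassifierConfig()
    windows = build_splice_windows(model, exon_number, window_cfg)
    kept_variants, audit = filter_variants(variants, filter_cfg)
    kept_fusions = filter_fusions(fusions, filter_cfg)
    splice_hits = splice_window_variants(kept_variants, model, windows)
    best_fusion: dict[str, FusionCall] = {}
    for f in kept_fusions:
        cur = best_fusion.get(f.patient_id)
        if cur is None or f.read_count > cur.read_count:
            best_fusion[f.patient_id] = f
    universe = list(patients) if patients is not None else sorted(
        set(best_fusion) | set(splice_hits))
    calls = [classify_metex14(best_fusion.get(pid), splice_hits.get(pid, ()),
                              clf_cfg, patient_id=pid)
             for pid in universe]
    coverage = dna_coverage_map(splice_hits, clf_cfg.coverage_metric)
    return calls, coverage, audit


def calls_to_frame(calls: Sequence[Metex14Call], config_fingerprint: str = "") -> pd.DataFrame:
    """Tabular (TSV-ready) view of per-patient calls."""
    return pd.DataFrame([{
        "patient_id": c.patient_id,
        "category": c.category.value,
        "rna_reads": c.rna_reads,
        "n_dna_splice_variants": len(c.dna_splice_variants),
        "rationale": c.rationale,
        "config_fingerprint": config_fingerprint,
    } for c in calls])
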