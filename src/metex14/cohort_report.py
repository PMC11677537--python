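"""Cohort-level prevalence tables and two-cohort comparisons.

Prevalence is per patient (a patient with several variants in a gene counts
once).  Cross-cohort proportion comparisons use a two-sided Fisher exact
test on the 2x2 table of carriers vs non-carriers — the reference cohort's
(count, n) pairs enter as plain configuration numbers, never downloaded.
Significance stars follow the usual 0.05 / 0.01 / 0.001 ladder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PrevalenceRow",
    "TwoCohortComparison",
    "gene_prevalence",
    "compare_prevalence",
    "significance_label",
    "clinical_significance_breakdown",
    "patient_gene_matrix",
    "write_report_bundle",
]

CLINICAL_CLASSES = ("actionable", "likely_actionable", "VUS", "benign/other")


@dataclass(frozen=True)
class PrevalenceRow:
    gene: str
    n_patients_with_variant: int
    n_cohort: int
    prevalence: float


@dataclass(frozen=True)
class TwoCohortComparison:
    gene: str
    a: tuple[int, int]
    b: tuple[int, int]
    p_value: float
    significance_label: str


def gene_prevalence(cohort_variants: Iterable[tuple[str, str]],
                    n_cohort: int,
                    genes: Sequence[str] | None = None) -> list[PrevalenceRow]:
    """Per-gene patient prevalence from (patient_id, gene) pairs.

    ``genes`` optionally fixes the gene list (so genes with zero carriers
    still get a row); otherwise genes are taken from the data.
    """
    if n_cohort <= 0:
        raise ValidationError("n_cohort must be positive")
    carriers: dict[str, set[str]] = {}
    for pid, gene in cohort_variants:
        carriers.setdefault(gene, set()).add(pid)
    gene_list = list(genes) if genes is not None else sorted(carriers)
    return [PrevalenceRow(g, len(carriers.get(g, ())), n_cohort,
                          len(carriers.get(g, ())) / n_cohort)
            for g in gene_list]


def significance_label(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_prevalence(gene: str, a: tuple[int, int],
                       b: tuple[int, int]) -> TwoCohortComparison:
    """Two-sided Fisher exact test of carrier proportions between cohorts.

    ``a`` and ``b`` are (carrier count, cohort size); the 2x2 table is
    [[count_a, n_a - count_a], [count_b, n_b - count_b]].
    """
    for count, n in (a, b):
        if n <= 0:
            raise ValidationError("cohort size must be positive")
        if not 0 <= count <= n:
            raise ValidationError(f"count {count} outside [0, {n}]")
    table = [[a[0], a[1] - a[0]], [b[0], b[1] - b[0]]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return TwoCohortComparison(gene, a, b, float(p), significance_label(float(p)))


def clinical_significance_breakdown(variants: Iterable[tuple[str, str]],
                                    denominator: int | None = None,
                                    ) -> dict[str, tuple[int, float]]:
    """Counts and percentages per clinical-significance class.

    ``variants`` holds (item_id, class) pairs — items may be variants or
    patients; the percentage denominator is an explicit parameter because
    published breakdowns do not always use the row count (default: number
    of distinct items supplied).
    """
    seen: dict[str, str] = {}
    for item, cls in variants:
        if cls not in CLINICAL_CLASSES:
            raise ValidationError(f"unknown clinical significance class {cls!r}")
        seen[item] = cls
    denom = denominator if denominator is not None else len(seen)
    out: dict[str, tuple[int, float]] = {}
    for cls in CLINICAL_CLASSES:
        count = sum(1 for c in seen.values() if c == cls)
        out[cls] = (count, 100.0 * count / denom if denom else 0.0)
    return out


def patient_gene_matrix(cohort_variants: Iterable[tuple[str, str]],
                        patients: Sequence[str],
                        genes: Sequence[str]) -> pd.DataFrame:
    """Oncoplot-style 0/1 patient x gene carrier matrix."""
    mat = pd.DataFrame(0, index=list(patients), columns=list(genes), dtype=int)
    for pid, gene in cohort_variants:
        if pid in mat.index and gene in mat.columns:
            mat.loc[pid, gene] = 1
    mat.index.name = "patient_id"
    return mat


def write_report_bundle(outdir, prevalence: Sequence[PrevalenceRow],
                        comparisons: Sequence[TwoCohortComparison],
                        breakdown: Mapping[str, tuple[int, float]] | None = None,
                        matrix: pd.DataFrame | None = None,
                        metadata: Mapping | None = None) -> None:
    """Serialize the report: prevalence TSV, comparison TSV, significance JSON,
    and the optional oncoplot matrix TSV."""
    import os
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame([{
        "gene": r.gene, "n_patients_with_variant": r.n_patients_with_variant,
        "n_cohort": r.n_cohort, "prevalence": r.prevalence,
        "prevalence_pct": round(100.0 * r.prevalence),  # whole-percent rendering
    } for r in prevalence]).to_csv(os.path.join(outdir, "prevalence.tsv"),
                                   sep="\t", index=False)
    pd.DataFrame([{
        "gene": c.gene, "count_a": c.a[0], "n_a": c.a[1],
        "count_b": c.b[0], "n_b": c.b[1],
        "p_value": float(f"{c.p_value:.3g}"), "significance": c.significance_label,
    } for c in comparisons]).to_csv(os.path.join(outdir, "comparison.tsv"),
                                    sep="\t", index=False)
    sig = {
        "test": "two-sided Fisher exact",
        "comparisons": {c.gene: {"p_value": float(f"{c.p_value:.3g}"),
                                 "label": c.significance_label} for c in comparisons},
    }
    if breakdown is not None:
        sig["clinical_significance_breakdown"] = {
            cls: {"count": cnt, "percentage": round(pct, 1)}
            for cls, (cnt, pct) in breakdown.items()}
    if metadata:
        sig["metadata"] = dict(metadata)
    with open(os.path.join(outdir, "significance.json"), "w") as fh:
        json.dump(sig, fh, indent=2)
    if matrix is not None:
        matrix.to_csv(os.path.join(outdir, "patient_gene_matrix.tsv"), sep="\t")
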